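system_id,component,part
1,n-hexane,1.00
1,ethyl acetate,1.50
1,methanol,1.25
1,water,1.25
2,n-hexane,1.00
2,ethyl acetate,2.33
2,methanol,1.67
2,water,1.67
3,n-hexane,1.00
3,ethyl acetate,1.50
3,methanol,1.00
3,water,1.50
4,n-hexane,1.00
4,ethyl acetate,2.33
4,methanol,1.33
4,water,2.00
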