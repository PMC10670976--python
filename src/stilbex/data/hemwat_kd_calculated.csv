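system_id,solute,K_D
1,trans-epsilon-viniferin,0.06
1,trans-resveratrol,0.21
2,trans-epsilon-viniferin,0.41
2,trans-resveratrol,0.65
3,trans-epsilon-viniferin,0.57
3,trans-resveratrol,0.85
4,trans-epsilon-viniferin,1.78
4,trans-resveratrol,1.66
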