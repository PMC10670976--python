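label,hba,hbd,ratio_num,ratio_den,water_wt_pct,preparable
Ch/Pdiol 1/5,choline chloride,"1,2-propanediol",1,5,0,true
B/Bdiol 1/1,betaine,"1,4-butanediol",1,1,30,true
B/Sor 1/1,betaine,sorbitol,1,1,30,true
Glu/U 1/3,glucose,urea,1,3,30,true
Glu/U 1/1,glucose,urea,1,1,60,true
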