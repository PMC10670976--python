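name,abbrev,role,molar_mass,liquid_molar_volume,density,provenance
water,H2O,solvent,18.015,18.05,0.9982,CRC-style reference value (25 C)
n-hexane,Hex,solvent,86.18,130.5,0.6606,CRC-style reference value (25 C)
ethyl acetate,EtOAc,solvent,88.11,97.7,0.902,CRC-style reference value (25 C)
methanol,MeOH,solvent,32.04,40.5,0.792,CRC-style reference value (25 C)
choline chloride,Ch,hba,139.62,130.0,,estimated subcooled-liquid volume (ion pair)
betaine,B,hba,117.15,98.0,,estimated subcooled-liquid volume
glucose,Glu,hba,180.16,115.0,,estimated subcooled-liquid volume
fructose,Fru,hba,180.16,113.0,,estimated subcooled-liquid volume
urea,U,hbd,60.06,45.5,,estimated subcooled-liquid volume
glycerol,Gly,hbd,92.09,73.0,1.261,CRC-style reference value (25 C)
"1,2-propanediol",Pdiol,hbd,76.09,73.4,1.036,CRC-style reference value (25 C)
"1,4-butanediol",Bdiol,hbd,90.12,88.6,1.017,CRC-style reference value (25 C)
sorbitol,Sor,hbd,182.17,119.0,,estimated subcooled-liquid volume
sucrose,Suc,hbd,342.30,215.0,,estimated subcooled-liquid volume
acetic acid,AA,hbd,60.05,57.2,1.049,CRC-style reference value (25 C)
lactic acid,LA,hbd,90.08,74.5,1.209,CRC-style reference value (25 C)
malic acid,MA,hbd,134.09,85.0,,estimated subcooled-liquid volume
citric acid,CA,hbd,192.12,114.0,,estimated subcooled-liquid volume
oxalic acid,OxA,hbd,90.03,48.0,,estimated subcooled-liquid volume
benzoic acid,BA,hbd,122.12,101.0,,estimated subcooled-liquid volume
adipic acid,AdA,hbd,146.14,108.0,,estimated subcooled-liquid volume
trans-resveratrol,res,solute,228.25,172.0,,estimated subcooled-liquid volume
trans-epsilon-viniferin,vin,solute,454.47,340.0,,estimated subcooled-liquid volume
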