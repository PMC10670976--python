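name,formula,monoisotopic_mass
trans-resveratrol,C14H12O3,228.0786
resveratrol dimer,C28H22O6,454.1416
ampelopsin A,C28H22O7,470.1366
restrytisol,C28H24O7,472.1522
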