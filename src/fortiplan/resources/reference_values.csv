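age_low,age_high,ar,ri,ul
4,11,7.5,10,50
11,18,7.5,10,100
18,70,7.5,10,100
75,120,7.5,20,100
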