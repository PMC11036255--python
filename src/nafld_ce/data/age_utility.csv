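age_lo,utility
18,0.922
30,0.901
40,0.871
50,0.842
60,0.823
70,0.790
80,0.736
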