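from_state,to_state,annual_probability,subpop
F0,F1,0.06,NAFL
F1,F2,0.06,NAFL
F2,F3,0.06,NAFL
F0,F4,0.003,NAFL
F1,F4,0.003,NAFL
F0,F1,0.12,NASH
F1,F2,0.12,NASH
F2,F3,0.12,NASH
F2,F4,0.02,NASH
F0,NASH,0.10,NAFL
F1,NASH,0.10,NAFL
F2,NASH,0.10,NAFL
F0,NAFL,0.06,NASH
F1,NAFL,0.06,NASH
F2,NAFL,0.06,NASH
F3,F4,0.12,
F3,DC,0.02,
F3,HCC,0.01,
F4,DC,0.06,
F4,HCC,0.02,
DC,HCC,0.03,
DC,LT,0.005,
HCC,LT,0.004,
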