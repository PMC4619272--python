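dilution,expected_copies_per_ul,observed_copies_per_ul,reported_efficiency_pct
D1,500,598,83
D2,100,115,87
D3,20,25.24,78
D4,4,5.4,74
D5,0.8,1.08,74
D6,0.15,0.13,115
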