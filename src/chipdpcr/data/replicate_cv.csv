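sample,intra_run_cv,inter_run_cv
Sample 1,0.004,0.05
Sample 2,0.033,0.02
Sample 3,0.009,0.02
Sample 4,0.008,0.07
Sample 5,0.142,0.04
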