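threshold_index,estimate,se
1,-2.649,0.017
2,-1.075,0.013
3,0.670,0.011
4,2.355,0.011
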