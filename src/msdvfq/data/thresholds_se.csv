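threshold_index,estimate,se
1,-2.675,0.021
2,-0.878,0.016
3,0.190,0.015
4,1.661,0.016
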