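threshold_index,estimate,se
1,-2.396,0.013
2,-0.796,0.010
3,0.640,0.009
4,2.187,0.009
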