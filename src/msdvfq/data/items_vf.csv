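item_id,measure,se
4,-2.893,0.091
5,2.368,0.031
6,1.056,0.031
7,-0.619,0.042
8,0.540,0.032
9,-0.138,0.042
10,-1.189,0.046
11,-1.135,0.039
12,-2.548,0.057
13,-2.016,0.044
14,-0.171,0.029
30,0.266,0.028
16,3.069,0.033
16A,2.172,0.029
A3,2.456,0.032
A4,0.519,0.029
A5,-1.093,0.040
A6,-0.085,0.035
A7,0.122,0.029
A8,-0.682,0.041
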