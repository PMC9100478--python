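item_id,measure,se
3,2.097,0.033
17,0.973,0.030
18,-0.277,0.031
19,-2.990,0.055
20,-1.170,0.032
21,1.829,0.029
22,1.147,0.028
23,-0.169,0.029
24,-0.310,0.030
25,-1.130,0.032
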