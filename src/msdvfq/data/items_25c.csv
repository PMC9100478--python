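item_id,native,domain,driving,recode,description,measure,se
3,q3,SE,0,frequency5_reverse,"How much time worrying about eyesight",1.892,0.031
4,q4,VF,0,severity5_reverse,"Amount of pain or discomfort in or around your eyes",-2.653,0.085
5,q5,VF,0,difficulty6,"Reading ordinary print in newspapers",2.057,0.028
6,q6,VF,0,difficulty6,"Doing work up close (e.g., cooking, sewing, fixing things around the house)",0.938,0.029
7,q7,VF,0,difficulty6,"Finding something on a crowded shelf",-0.583,0.040
8,q8,VF,0,difficulty6,"Reading street signs or the name of stores",0.467,0.030
9,q9,VF,0,difficulty6,"Going down steps, stairs, or curbs in dim light or at night",-0.134,0.039
10,q10,VF,0,difficulty6,"Noticing objects off to the side while you are walking along",-1.113,0.044
11,q11,VF,0,difficulty6,"Seeing how people react to things you say",-1.077,0.037
12,q12,VF,0,difficulty6,"Picking out and matching your own clothes",-2.357,0.054
13,q13,VF,0,difficulty6,"Visiting with people in their homes, at parties, or in restaurants",-1.879,0.042
14,q14,VF,0,difficulty6,"Going out to see movies, plays, or sports events",-0.224,0.028
30,q15c,VF,1,driving,"Driving during the daytime in familiar places",0.104,0.026
16,q16,VF,1,difficulty6,"Driving at night",2.527,0.028
16A,q16a,VF,1,difficulty6,"Driving in difficult conditions (e.g., bad weather, during rush hour, on the freeway)",1.803,0.026
17,q17,SE,0,agreement5,"Accomplish less than you would like because of vision",0.956,0.027
18,q18,SE,0,agreement5,"Limited in how long you can work or do other activities because of your vision",-0.103,0.029
19,q19,SE,0,agreement5,"Pain or discomfort in or around your eyes keeps you from doing what you'd like",-2.469,0.052
20,q20,SE,0,agreement5,"Stay home most of the time because of your eyesight",-0.857,0.031
21,q21,SE,0,agreement5,"Frustrated a lot because of eyesight",1.701,0.026
22,q22,SE,0,agreement5,"Less control over what you do because of eyesight",1.137,0.026
23,q23,SE,0,agreement5,"Rely too much on what other people tell you because of eyesight",0.010,0.027
24,q24,SE,0,agreement5,"Need a lot of help from others because of eyesight",-0.113,0.028
25,q25,SE,0,agreement5,"Worry about doing things that will embarrass you because of your eyesight",-0.821,0.030
A3,a3,VF,0,difficulty6,"Reading small print in a telephone book or on a medicine bottle or legal forms",2.137,0.029
A4,a4,VF,0,difficulty6,"Figuring out whether bills you receive are accurate",0.408,0.027
A5,a5,VF,0,difficulty6,"Shaving, styling hair, putting on makeup",-1.038,0.038
A6,a6,VF,0,difficulty6,"Recognizing people you know from across a room because of eyesight",-0.115,0.033
A7,a7,VF,0,difficulty6,"Taking part in active sports or other outdoor activities (e.g., golf, bowling, jogging) because of eyesight",0.042,0.027
A8,a8,VF,0,difficulty6,"Seeing and enjoying programs on TV",-0.645,0.039
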