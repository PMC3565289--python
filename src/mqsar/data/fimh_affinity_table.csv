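compound_no,exp_pic50,pred_pic50,residual
1,7.3,7.6,0.3
2,7.0,7.4,0.4
3,7.5,7.5,0
4,6.7,6.5,-0.2
5,8.5,7.7,-0.8
6,8.6,7.8,-0.8
7,6.2,6.7,0.5
8,7.8,7.0,-0.8
9,8.0,7.4,-0.6
10,7.5,7.2,-0.3
11,7.8,7.3,-0.5
12,8.1,7.0,-1.1
13,7.8,7.5,-0.3
14,6.6,7.0,0.4
15,6.8,6.6,-0.2
16,6.4,6.2,-0.2
17,5.5,6.0,0.5
18,7.2,6.9,-0.3
19,6.2,7.1,0.9
20,6.4,6.7,0.3
21,6.9,7.1,0.2
22,6.4,7.1,0.7
23,6.3,7.1,0.8
24,6.3,7.0,0.7
25,6.8,7.4,0.6
26,6.5,6.7,0.2
27,7.2,6.8,-0.4
28,8.6,8.0,-0.6
29,6.1,6.8,0.7
30,6.6,7.3,0.7
31,6.8,6.8,0
32,7.0,7.2,0.2
33,6.7,6.9,0.2
34,6.8,6.8,0
35,6.7,6.7,0
36,6.5,6.3,-0.2
37,6.6,6.8,0.2
38,6.6,6.6,0
39,6.8,7.3,0.5
40,6.7,6.5,-0.2
41,6.3,6.5,0.2
42,8.0,7.7,-0.3
43,8.2,7.5,-0.7
44,7.7,7.6,-0.1
45,7.6,7.5,-0.1
46,8.3,7.8,-0.5
47,7.7,7.4,-0.3
48,7.4,7.3,-0.1
49,7.5,7.3,-0.2
50,7.8,7.4,-0.4
51,8.3,7.9,-0.4
52,8.0,7.4,-0.6
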