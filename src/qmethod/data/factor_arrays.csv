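statement_id,factor_1,factor_2,factor_3,factor_4,factor_5
1,2,3,5,3,3
2,-3,-1,-3,-1,-5
3,-2,0,-1,0,-1
4,2,2,4,3,0
5,-2,1,-2,1,-4
6,-1,1,1,-1,-2
7,-1,2,0,-1,2
8,-2,2,2,0,-2
9,-1,4,2,2,-3
10,0,2,0,3,-3
11,-1,0,2,-3,3
12,-2,1,3,-3,0
13,-1,0,2,-2,1
14,-2,-1,0,-1,-1
15,-5,-2,-2,-5,0
16,-3,-2,-2,-4,-1
17,3,-2,1,2,2
18,2,0,1,0,1
19,1,3,3,4,0
20,3,4,-1,-4,2
21,4,3,0,-2,-1
22,0,1,-5,0,5
23,0,0,-4,1,4
24,1,-2,-1,1,0
25,5,5,0,-3,0
26,-3,1,0,-2,-2
27,-4,-2,-4,-2,0
28,2,0,-1,0,2
29,0,0,-2,-1,1
30,1,-1,-3,2,1
31,-1,-4,-3,1,0
32,0,-1,-2,2,2
33,1,-4,0,1,-2
34,3,-3,0,-1,-1
35,0,-3,-1,-2,-2
36,1,-5,-1,0,1
37,4,-1,4,2,4
38,2,-3,1,1,3
39,0,1,3,4,1
40,0,0,2,5,-4
41,1,-1,1,0,-3
42,-4,2,1,0,-1
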