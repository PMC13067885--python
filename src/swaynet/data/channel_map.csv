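channel,hemisphere,region
8,L,PFC
9,L,PFC
10,L,PFC
11,L,PFC
12,L,PFC
20,L,PFC
22,L,PFC
23,L,PFC
24,L,PFC
25,L,PFC
30,L,S1
32,L,S1
33,L,S1
31,L,M1
44,L,M1
13,L,PMC
14,L,PMC
27,L,PMC
43,L,PMC
26,L,PMC
39,L,V
40,L,V
41,L,V
47,L,V
48,L,V
3,R,PFC
17,R,PFC
19,R,PFC
4,R,PFC
18,R,PFC
5,R,PFC
7,R,PFC
21,R,PFC
6,R,PFC
34,R,S1
15,R,S1
35,R,S1
16,R,M1
42,R,M1
1,R,PMC
2,R,PMC
28,R,PMC
29,R,PMC
45,R,PMC
36,R,V
37,R,V
38,R,V
46,R,V
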