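parcel_id,network,hemisphere
1,DEF,L
2,DEF,L
3,DEF,L
4,DEF,L
5,DEF,L
6,DEF,L
7,DEF,L
8,DEF,L
9,SOM,L
10,SOM,L
11,SOM,L
12,SOM,L
13,SOM,L
14,SOM,L
15,SOM,L
16,SVA,L
17,SVA,L
18,SVA,L
19,SVA,L
20,SVA,L
21,SVA,L
22,SVA,L
23,DA,L
24,DA,L
25,DA,L
26,DA,L
27,DA,L
28,DA,L
29,DA,L
30,VIS,L
31,VIS,L
32,VIS,L
33,VIS,L
34,VIS,L
35,VIS,L
36,VIS,L
37,LIM,L
38,LIM,L
39,LIM,L
40,LIM,L
41,LIM,L
42,LIM,L
43,LIM,L
44,CON,L
45,CON,L
46,CON,L
47,CON,L
48,CON,L
49,CON,L
50,CON,L
51,DEF,R
52,DEF,R
53,DEF,R
54,DEF,R
55,DEF,R
56,DEF,R
57,DEF,R
58,DEF,R
59,SOM,R
60,SOM,R
61,SOM,R
62,SOM,R
63,SOM,R
64,SOM,R
65,SOM,R
66,SVA,R
67,SVA,R
68,SVA,R
69,SVA,R
70,SVA,R
71,SVA,R
72,SVA,R
73,DA,R
74,DA,R
75,DA,R
76,DA,R
77,DA,R
78,DA,R
79,DA,R
80,VIS,R
81,VIS,R
82,VIS,R
83,VIS,R
84,VIS,R
85,VIS,R
86,VIS,R
87,LIM,R
88,LIM,R
89,LIM,R
90,LIM,R
91,LIM,R
92,LIM,R
93,LIM,R
94,CON,R
95,CON,R
96,CON,R
97,CON,R
98,CON,R
99,CON,R
100,CON,R
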