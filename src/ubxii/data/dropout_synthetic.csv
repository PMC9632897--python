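course_id,y,x2,x3,x4
1,0.771494,0.000000,1.000000,1.000000
2,0.707182,0.000000,1.000000,0.000000
3,0.725392,31.000000,1.000000,0.000000
4,0.871179,33.000000,0.000000,1.000000
5,0.585888,0.000000,0.000000,0.000000
6,0.495086,0.000000,0.000000,0.000000
7,0.766720,25.000000,0.000000,0.000000
8,0.398306,0.000000,0.000000,0.000000
9,0.586378,9.000000,1.000000,0.000000
10,0.586456,12.000000,1.000000,0.000000
11,0.481928,0.000000,0.000000,0.000000
12,0.231417,31.000000,0.000000,0.000000
13,0.704164,19.000000,0.000000,1.000000
14,0.623074,0.000000,0.000000,1.000000
15,0.345917,0.000000,0.000000,0.000000
16,0.623057,48.000000,1.000000,0.000000
17,0.781004,92.000000,0.000000,0.000000
18,0.428066,0.000000,0.000000,0.000000
19,0.912453,19.000000,1.000000,0.000000
20,0.768668,0.000000,1.000000,1.000000
21,0.699487,0.000000,1.000000,0.000000
22,0.383728,0.000000,0.000000,0.000000
23,0.762410,0.000000,1.000000,0.000000
24,0.715448,0.000000,1.000000,1.000000
25,0.527014,0.000000,1.000000,0.000000
26,0.569087,15.000000,1.000000,0.000000
27,0.445611,0.000000,1.000000,0.000000
28,0.623329,0.000000,0.000000,0.000000
29,0.592825,0.000000,1.000000,0.000000
30,0.756601,41.000000,1.000000,1.000000
31,0.543391,19.000000,0.000000,0.000000
32,0.632504,9.000000,1.000000,0.000000
33,0.635048,7.000000,1.000000,0.000000
34,0.710605,3.000000,1.000000,0.000000
35,0.348366,52.000000,0.000000,0.000000
36,0.864089,66.000000,1.000000,1.000000
37,0.167074,0.000000,0.000000,0.000000
38,0.851036,1.000000,0.000000,0.000000
39,0.683351,0.000000,1.000000,0.000000
40,0.700602,0.000000,1.000000,1.000000
41,0.826062,0.000000,1.000000,0.000000
42,0.782314,48.000000,1.000000,1.000000
43,0.636729,0.000000,0.000000,1.000000
44,0.437006,24.000000,1.000000,0.000000
45,0.420398,0.000000,0.000000,0.000000
46,0.714533,0.000000,1.000000,0.000000
47,0.440127,0.000000,1.000000,0.000000
48,0.857041,0.000000,1.000000,1.000000
49,0.449857,0.000000,0.000000,0.000000
50,0.765036,12.000000,1.000000,0.000000
51,0.474594,0.000000,1.000000,0.000000
52,0.811940,0.000000,1.000000,0.000000
53,0.749637,91.000000,0.000000,0.000000
54,0.161363,0.000000,0.000000,0.000000
55,0.784225,0.000000,1.000000,1.000000
56,0.650539,0.000000,1.000000,1.000000
57,0.842203,0.000000,1.000000,1.000000
58,0.565303,0.000000,1.000000,0.000000
59,0.734840,0.000000,1.000000,0.000000
60,0.891674,0.000000,1.000000,1.000000
61,0.476036,0.000000,1.000000,0.000000
62,0.662928,0.000000,0.000000,0.000000
63,0.428157,0.000000,0.000000,0.000000
64,0.573102,0.000000,1.000000,0.000000
65,0.825106,0.000000,1.000000,1.000000
66,0.942333,0.000000,1.000000,1.000000
67,0.583238,0.000000,0.000000,0.000000
68,0.717955,0.000000,1.000000,1.000000
69,0.003417,1.000000,0.000000,0.000000
70,0.527137,0.000000,0.000000,1.000000
71,0.379953,1.000000,0.000000,0.000000
72,0.493645,0.000000,0.000000,1.000000
73,0.427571,13.000000,1.000000,0.000000
74,0.863496,14.000000,1.000000,0.000000
75,0.460805,0.000000,1.000000,0.000000
76,0.598845,21.000000,1.000000,0.000000
77,0.827775,0.000000,0.000000,0.000000
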