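age,multiplier
0,1.0
1,1.0
2,1.0
3,1.0
4,1.0
5,1.0
6,1.0
7,1.0
8,1.0
9,1.0
10,1.0
11,1.0
12,1.0
13,1.0
14,1.0
15,1.0
16,1.0
17,1.0
18,1.0
19,1.0
20,1.0
21,1.0
22,1.0
23,1.0
24,1.0
25,1.0
26,1.0
27,1.0
28,1.0
29,1.0
30,1.0
31,1.0
32,1.0
33,1.0
34,1.0
35,1.0
36,1.0
37,1.0
38,1.0
39,1.0
40,1.0
41,1.0
42,1.0
43,0.996
44,0.992
45,0.988
46,0.984
47,0.98
48,0.976
49,0.972
50,0.968
51,0.964
52,0.96
53,0.956
54,0.952
55,0.948
56,0.944
57,0.94
58,0.9359999999999999
59,0.9319999999999999
60,0.9279999999999999
61,0.924
62,0.92
63,0.916
64,0.912
65,0.908
66,0.904
67,0.9
68,0.896
69,0.892
70,0.888
71,0.884
72,0.88
73,0.876
74,0.872
75,0.868
76,0.864
77,0.86
78,0.856
79,0.852
80,0.848
81,0.844
82,0.84
83,0.836
84,0.832
85,0.828
86,0.8240000000000001
87,0.8200000000000001
88,0.8160000000000001
89,0.812
90,0.808
91,0.804
92,0.8
93,0.796
94,0.792
95,0.788
96,0.784
97,0.78
98,0.776
99,0.772
100,0.768
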