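age,qx
0,0.00031445055005918654
1,0.00031597504767855167
2,0.00031765987540777196
3,0.00031952189471284864
4,0.00032157974026325586
5,0.00032385400639156625
6,0.00032636745315783866
7,0.0003291452340766776
8,0.00033221514778603023
9,0.0003356079161718206
10,0.00033935749172853136
11,0.00034350139722849615
12,0.00034808110109163515
13,0.0003531424322078536
14,0.00035873603835379075
15,0.00036491789278314535
16,0.0003717498540469766
17,0.000379300284632067
18,0.000387644734591297
19,0.00039686669698335564
20,0.0004070584426569823
21,0.0004183219426995288
22,0.0004307698877401567
23,0.00044452681426065954
24,0.0004597303491228333
25,0.00047653258469426696
26,0.0004951015982421758
27,0.0005156231306907566
28,0.0005383024414061799
29,0.0005633663574047265
30,0.0005910655372897144
31,0.0006216769723255133
32,0.0006555067493746458
33,0.000692893102979597
34,0.0007342097866804842
35,0.0007798697967538182
36,0.0008303294849648646
37,0.0008860931006666739
38,0.0009477178066935599
39,0.001015819218017855
40,0.0010910775170940301
41,0.0011742442052572466
42,0.0012661495554990854
43,0.0013677108384712033
44,0.0014799414006976264
45,0.0016039606817686014
46,0.0017410052657869102
47,0.0018924410715857043
48,0.002059776796297319
49,0.00224467873775569
50,0.0024489871330237722
51,0.002674734163073622
52,0.0029241637873582693
53,0.0031997535867094307
54,0.0035042388086878873
55,0.0038406388261831292
56,0.004212286237668561
57,0.0046228588559849015
58,0.005076414851733491
59,0.005577431337117855
60,0.006130846696143721
61,0.006742106987099761
62,0.0074172167627643
63,0.008162794672187612
64,0.008986134224421183
65,0.009895270108205234
66,0.01089905047112727
67,0.012007215565543738
68,0.013230483164653029
69,0.01458064113808355
70,0.01607064754921439
71,0.017714738592522705
72,0.019528544624084265
73,0.02152921444655731
74,0.023735547885069153
75,0.026168136524655994
76,0.028849512264082833
77,0.03180430306415405
78,0.03505939491834198
79,0.03864409863502949
80,0.04259031947705105
81,0.046932727036475774
82,0.05170892190948173
83,0.056959594754516285
84,0.06272867214203026
85,0.06906344221049188
86,0.0760146515063399
87,0.08363656248279483
88,0.0919869589471991
89,0.10112708427143513
90,0.1111214944224298
91,0.12203780485942906
92,0.13394630714274935
93,0.1469194278097491
94,0.16103099886075012
95,0.17635530629939689
96,0.19296588092362854
97,0.21093399441861516
98,0.23032682435623508
99,0.2512052547122081
100,1.0
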