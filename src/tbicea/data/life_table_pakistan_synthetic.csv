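age,qx
0,0.00207783829903907
1,0.0020850948975442707
2,0.0020930110365792176
3,0.0021016466547509882
4,0.002111067136713829
5,0.0021213438077832825
6,0.00213255447343097
7,0.002144784007724887
8,0.0021581249951448944
9,0.0021726784306052016
10,0.002188554482949301
11,0.00220587332765676
12,0.002224766055017535
13,0.002245375660590465
14,0.002267858125376554
15,0.002292383593800129
16,0.002319137658318593
17,0.002348322760265642
18,0.0023801597173962463
19,0.0024148893895250545
20,0.002452774494672294
21,0.002494101589223585
22,0.0025391832268131243
23,0.002588360311932325
24,0.0026420046656789875
25,0.0027005218225879535
26,0.0027643540791443266
27,0.002833983816371566
28,0.0029099371208357594
29,0.0029927877305083728
30,0.003083161334202611
31,0.003181740255760679
32,0.0032892685568125524
33,0.0034065575947912485
34,0.0035344920759605714
35,0.003674036646519996
36,0.003826243068403068
37,0.0039922580301829935
38,0.004173331647575496
39,0.004370826712359777
40,0.004586228753166388
41,0.004821156976477892
42,0.005077376161379932
43,0.005356809587061306
44,0.005661553077801917
45,0.0059938902561709195
46,0.006356309101368196
47,0.006751519916040061
48,0.007182474811428086
49,0.007652388827302348
50,0.008164762809692694
51,0.008723408175852043
52,0.009332473702007626
53,0.00999647447510843
54,0.010720323154714162
55,0.011509363695128227
56,0.012369407680499767
57,0.013306773426486118
58,0.014328328000689838
59,0.015441532309824035
60,0.01665448939371983
61,0.01797599605397404
62,0.01941559792722347
63,0.020983648088500617
64,0.0226913692374342
65,0.024550919477518418
66,0.02657546164432778
67,0.028779236070108904
68,0.031177636587006452
69,0.03378728946624987
70,0.03662613486249755
71,0.03971351017729685
72,0.043070234568908794
73,0.046718693612695095
74,0.05068292285155329
75,0.05498868866376405
76,0.05966356450996502
77,0.06473700019550599
78,0.07024038129284416
79,0.07620707530493753
80,0.08267246050953325
81,0.08967393270194057
82,0.0972508842485511
83,0.10544464897643302
84,0.11429840546168613
85,0.12385703025298045
86,0.13416689149716055
87,0.14527557235208766
88,0.1572315125229211
89,0.1700835553039497
90,0.1838803867321932
91,0.1986698529699792
92,0.21449814196992745
93,0.23140881600923247
94,0.2494416830196141
95,0.2686314970316819
96,0.28900648178121635
97,0.3105866769040069
98,0.3333821135074587
99,0.35739083557982476
100,1.0
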