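age,qx
18,0.000911
19,0.000922
20,0.000934
21,0.000947
22,0.000962
23,0.000978
24,0.000996
25,0.001015
26,0.001036
27,0.001060
28,0.001086
29,0.001114
30,0.001146
31,0.001180
32,0.001218
33,0.001260
34,0.001306
35,0.001356
36,0.001411
37,0.001472
38,0.001539
39,0.001613
40,0.001694
41,0.001783
42,0.001881
43,0.001989
44,0.002107
45,0.002238
46,0.002381
47,0.002538
48,0.002712
49,0.002902
50,0.003112
51,0.003342
52,0.003595
53,0.003874
54,0.004180
55,0.004517
56,0.004888
57,0.005295
58,0.005743
59,0.006236
60,0.006777
61,0.007373
62,0.008028
63,0.008748
64,0.009541
65,0.010412
66,0.011370
67,0.012423
68,0.013581
69,0.014855
70,0.016256
71,0.017796
72,0.019490
73,0.021352
74,0.023401
75,0.025653
76,0.028130
77,0.030853
78,0.033849
79,0.037142
80,0.040764
81,0.044747
82,0.049126
83,0.053943
84,0.059239
85,0.065063
86,0.071467
87,0.078509
88,0.086254
89,0.094770
90,0.104135
91,0.114433
92,0.125758
93,0.138211
94,0.151905
95,0.166964
96,0.183524
97,0.201734
98,0.221759
99,0.243779
100,0.267995
101,0.294623
102,0.323905
103,0.356105
104,0.391514
105,0.430453
106,0.473271
107,0.520357
108,0.572136
109,0.629074
110,1.000000
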