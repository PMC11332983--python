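# US all-population annual background mortality, q(age).
# Gompertz-Makeham smooth (q = 1 - exp(-(A + B*exp(C*age)))) calibrated by
# least squares to published US total-population period life table anchors
# (q40=0.0021, q50=0.0044, q60=0.0098, q70=0.0215, q80=0.0535, q90=0.1480,
#  q99=0.320). Swappable: any CSV with columns age,qx is accepted.
age,qx
40,0.002169
41,0.002291
42,0.002426
43,0.002574
44,0.002737
45,0.002917
46,0.003115
47,0.003333
48,0.003573
49,0.003838
50,0.004129
51,0.004451
52,0.004804
53,0.005194
54,0.005623
55,0.006096
56,0.006616
57,0.007189
58,0.007820
59,0.008515
60,0.009280
61,0.010123
62,0.011050
63,0.012071
64,0.013194
65,0.014430
66,0.015791
67,0.017288
68,0.018934
69,0.020745
70,0.022737
71,0.024927
72,0.027334
73,0.029979
74,0.032885
75,0.036077
76,0.039582
77,0.043429
78,0.047650
79,0.052280
80,0.057354
81,0.062914
82,0.069002
83,0.075665
84,0.082950
85,0.090911
86,0.099603
87,0.109083
88,0.119413
89,0.130657
90,0.142879
91,0.156147
92,0.170528
93,0.186091
94,0.202900
95,0.221019
96,0.240506
97,0.261414
98,0.283785
99,0.307650
100,0.333026
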