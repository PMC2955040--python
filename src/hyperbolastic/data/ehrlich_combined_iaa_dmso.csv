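time,weight
9.0,0.21
13.0,0.39
17.0,0.49
21.0,0.65
29.0,0.89
33.0,1.13
37.0,1.49
40.0,1.89
43.0,2.31
49.0,3.05
55.0,4.05
57.0,4.51
60.0,4.96
66.0,5.91
72.0,6.86
74.0,7.09
78.0,7.21
82.0,7.35
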