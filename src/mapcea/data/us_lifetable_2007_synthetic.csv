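age,qx
20,0.0002539300984333011
21,0.0002764580319127392
22,0.0003009845775692498
23,0.00032768704641265026
24,0.00035675847996544265
25,0.00038840904582775613
26,0.00042286755705271857
27,0.00046038312631635356
28,0.0005012269668405789
29,0.0005456943530888105
30,0.00059410675540873
31,0.0006468141640542955
32,0.0007041976193881695
33,0.0007666719665562833
34,0.0008346888545490496
35,0.0009087400013304877
36,0.0009893607486400275
37,0.0010771339321659025
38,0.0011726940950689733
39,0.0012767320753180257
40,0.00139
41,0.0015133167227107743
42,0.0016475737433353079
43,0.0017937416530133168
44,0.0019528771508833952
45,0.002126130683332096
46,0.002314754760974782
47,0.002520113013494618
48,0.0027436900478003223
49,0.002987102180770756
50,0.0032521091241771278
51,0.0035406267062572205
52,0.0038547407219103737
53,0.00419672201164113
54,0.004569042878262535
55,0.004974394960041196
56,0.005415708689495349
57,0.005896174478520404
58,0.006419265782996696
59,0.006988764213621563
60,0.007608786874500809
61,0.008283816127139798
62,0.009018731995008529
63,0.009818847442944683
64,0.010689946786441806
65,0.011638327508496898
66,0.012670845786326023
67,0.01379496605707664
68,0.015018814980864454
69,0.016351240191252715
70,0.01780187425790162
71,0.01938120432379638
72,0.02110064792048592
73,0.022972635509427096
74,0.02501070034615494
75,0.027229576316938432
76,0.029645304455217392
77,0.03227534890786525
78,0.035138723189638434
79,0.03825612763855015
80,0.041650099065881865
81,0.04534517368270462
82,0.04936806448076359
83,0.05374785435007434
84,0.0585162063293457
85,0.06370759250920352
86,0.06935954324303693
87,0.07551291846709991
88,0.08221220309133635
89,0.08950582859641273
90,0.09744652316189611
91,0.1060916928567771
92,0.11550383664809782
93,0.12575099822792807
94,0.1369072579251055
95,0.14905326825794193
96,0.16227683699959608
97,0.1766735619712944
98,0.1923475221525454
99,0.20941203010462447
100,0.22799045114686356
101,0.24821709520785784
102,0.2702381877990961
103,0.29421292713052294
104,0.3203146350102926
105,0.34873200984897396
106,0.37967049082661203
107,0.4133537430846903
108,0.45002527467996756
109,0.4899501969897154
110,0.5334171412949456
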