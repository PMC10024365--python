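age_months,L,M,S
0.0,1.0,16.0,0.1
3.0,1.0,17.909322,0.1
6.0,1.0,19.579922,0.1
9.0,1.0,21.042,0.1
12.0,1.0,22.321429,0.1
15.0,1.0,23.440454,0.1
18.0,1.0,24.418271,0.1
21.0,1.0,25.271498,0.1
24.0,1.0,26.014568,0.1
27.0,1.0,26.660053,0.1
30.0,1.0,27.218935,0.1
33.0,1.0,27.700831,0.1
36.0,1.0,28.114187,0.1
39.0,1.0,28.466435,0.1
42.0,1.0,28.764134,0.1
45.0,1.0,29.01308,0.1
48.0,1.0,29.218408,0.1
51.0,1.0,29.384676,0.1
54.0,1.0,29.515939,0.1
57.0,1.0,29.615806,0.1
60.0,1.0,29.6875,0.1
63.0,1.0,29.7339,0.1
66.0,1.0,29.757585,0.1
69.0,1.0,29.760863,0.1
72.0,1.0,29.745809,0.1
75.0,1.0,29.714286,0.1
78.0,1.0,29.667971,0.1
81.0,1.0,29.608376,0.1
84.0,1.0,29.536862,0.1
87.0,1.0,29.45466,0.1
90.0,1.0,29.362881,0.1
93.0,1.0,29.262531,0.1
96.0,1.0,29.154519,0.1
99.0,1.0,29.039671,0.1
102.0,1.0,28.918733,0.1
105.0,1.0,28.792385,0.1
108.0,1.0,28.661243,0.1
111.0,1.0,28.525864,0.1
114.0,1.0,28.386759,0.1
117.0,1.0,28.244388,0.1
120.0,1.0,28.099174,0.1
123.0,1.0,27.951497,0.1
126.0,1.0,27.801707,0.1
129.0,1.0,27.650121,0.1
132.0,1.0,27.497027,0.1
135.0,1.0,27.342689,0.1
138.0,1.0,27.187346,0.1
141.0,1.0,27.031215,0.1
144.0,1.0,26.874496,0.1
147.0,1.0,26.71737,0.1
150.0,1.0,26.56,0.1
153.0,1.0,26.402537,0.1
156.0,1.0,26.245117,0.1
159.0,1.0,26.087864,0.1
162.0,1.0,25.93089,0.1
165.0,1.0,25.774297,0.1
168.0,1.0,25.618178,0.1
171.0,1.0,25.462616,0.1
174.0,1.0,25.307688,0.1
177.0,1.0,25.153462,0.1
180.0,1.0,25.0,0.1
183.0,1.0,24.847357,0.1
186.0,1.0,24.695584,0.1
189.0,1.0,24.544725,0.1
192.0,1.0,24.394821,0.1
195.0,1.0,24.245906,0.1
198.0,1.0,24.098014,0.1
201.0,1.0,23.951171,0.1
204.0,1.0,23.805402,0.1
207.0,1.0,23.660728,0.1
210.0,1.0,23.51717,0.1
213.0,1.0,23.374741,0.1
216.0,1.0,23.233456,0.1
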