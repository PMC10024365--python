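age_months,L,M,S
0.0,1.0,50.0,0.04
3.0,1.0,51.5,0.04
6.0,1.0,53.0,0.04
9.0,1.0,54.5,0.04
12.0,1.0,56.0,0.04
15.0,1.0,57.5,0.04
18.0,1.0,59.0,0.04
21.0,1.0,60.5,0.04
24.0,1.0,62.0,0.04
27.0,1.0,63.5,0.04
30.0,1.0,65.0,0.04
33.0,1.0,66.5,0.04
36.0,1.0,68.0,0.04
39.0,1.0,69.5,0.04
42.0,1.0,71.0,0.04
45.0,1.0,72.5,0.04
48.0,1.0,74.0,0.04
51.0,1.0,75.5,0.04
54.0,1.0,77.0,0.04
57.0,1.0,78.5,0.04
60.0,1.0,80.0,0.04
63.0,1.0,81.5,0.04
66.0,1.0,83.0,0.04
69.0,1.0,84.5,0.04
72.0,1.0,86.0,0.04
75.0,1.0,87.5,0.04
78.0,1.0,89.0,0.04
81.0,1.0,90.5,0.04
84.0,1.0,92.0,0.04
87.0,1.0,93.5,0.04
90.0,1.0,95.0,0.04
93.0,1.0,96.5,0.04
96.0,1.0,98.0,0.04
99.0,1.0,99.5,0.04
102.0,1.0,101.0,0.04
105.0,1.0,102.5,0.04
108.0,1.0,104.0,0.04
111.0,1.0,105.5,0.04
114.0,1.0,107.0,0.04
117.0,1.0,108.5,0.04
120.0,1.0,110.0,0.04
123.0,1.0,111.5,0.04
126.0,1.0,113.0,0.04
129.0,1.0,114.5,0.04
132.0,1.0,116.0,0.04
135.0,1.0,117.5,0.04
138.0,1.0,119.0,0.04
141.0,1.0,120.5,0.04
144.0,1.0,122.0,0.04
147.0,1.0,123.5,0.04
150.0,1.0,125.0,0.04
153.0,1.0,126.5,0.04
156.0,1.0,128.0,0.04
159.0,1.0,129.5,0.04
162.0,1.0,131.0,0.04
165.0,1.0,132.5,0.04
168.0,1.0,134.0,0.04
171.0,1.0,135.5,0.04
174.0,1.0,137.0,0.04
177.0,1.0,138.5,0.04
180.0,1.0,140.0,0.04
183.0,1.0,141.5,0.04
186.0,1.0,143.0,0.04
189.0,1.0,144.5,0.04
192.0,1.0,146.0,0.04
195.0,1.0,147.5,0.04
198.0,1.0,149.0,0.04
201.0,1.0,150.5,0.04
204.0,1.0,152.0,0.04
207.0,1.0,153.5,0.04
210.0,1.0,155.0,0.04
213.0,1.0,156.5,0.04
216.0,1.0,158.0,0.04
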