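age_months,L,M,S
0.0,1.0,4.0,0.11
3.0,1.0,4.75,0.11
6.0,1.0,5.5,0.11
9.0,1.0,6.25,0.11
12.0,1.0,7.0,0.11
15.0,1.0,7.75,0.11
18.0,1.0,8.5,0.11
21.0,1.0,9.25,0.11
24.0,1.0,10.0,0.11
27.0,1.0,10.75,0.11
30.0,1.0,11.5,0.11
33.0,1.0,12.25,0.11
36.0,1.0,13.0,0.11
39.0,1.0,13.75,0.11
42.0,1.0,14.5,0.11
45.0,1.0,15.25,0.11
48.0,1.0,16.0,0.11
51.0,1.0,16.75,0.11
54.0,1.0,17.5,0.11
57.0,1.0,18.25,0.11
60.0,1.0,19.0,0.11
63.0,1.0,19.75,0.11
66.0,1.0,20.5,0.11
69.0,1.0,21.25,0.11
72.0,1.0,22.0,0.11
75.0,1.0,22.75,0.11
78.0,1.0,23.5,0.11
81.0,1.0,24.25,0.11
84.0,1.0,25.0,0.11
87.0,1.0,25.75,0.11
90.0,1.0,26.5,0.11
93.0,1.0,27.25,0.11
96.0,1.0,28.0,0.11
99.0,1.0,28.75,0.11
102.0,1.0,29.5,0.11
105.0,1.0,30.25,0.11
108.0,1.0,31.0,0.11
111.0,1.0,31.75,0.11
114.0,1.0,32.5,0.11
117.0,1.0,33.25,0.11
120.0,1.0,34.0,0.11
123.0,1.0,34.75,0.11
126.0,1.0,35.5,0.11
129.0,1.0,36.25,0.11
132.0,1.0,37.0,0.11
135.0,1.0,37.75,0.11
138.0,1.0,38.5,0.11
141.0,1.0,39.25,0.11
144.0,1.0,40.0,0.11
147.0,1.0,40.75,0.11
150.0,1.0,41.5,0.11
153.0,1.0,42.25,0.11
156.0,1.0,43.0,0.11
159.0,1.0,43.75,0.11
162.0,1.0,44.5,0.11
165.0,1.0,45.25,0.11
168.0,1.0,46.0,0.11
171.0,1.0,46.75,0.11
174.0,1.0,47.5,0.11
177.0,1.0,48.25,0.11
180.0,1.0,49.0,0.11
183.0,1.0,49.75,0.11
186.0,1.0,50.5,0.11
189.0,1.0,51.25,0.11
192.0,1.0,52.0,0.11
195.0,1.0,52.75,0.11
198.0,1.0,53.5,0.11
201.0,1.0,54.25,0.11
204.0,1.0,55.0,0.11
207.0,1.0,55.75,0.11
210.0,1.0,56.5,0.11
213.0,1.0,57.25,0.11
216.0,1.0,58.0,0.11
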