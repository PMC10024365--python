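height_cm,L,M,S
45.0,1.0,1.5,0.11
47.5,1.0,2.75,0.11
50.0,1.0,4.0,0.11
52.5,1.0,5.25,0.11
55.0,1.0,6.5,0.11
57.5,1.0,7.75,0.11
60.0,1.0,9.0,0.11
62.5,1.0,10.25,0.11
65.0,1.0,11.5,0.11
67.5,1.0,12.75,0.11
70.0,1.0,14.0,0.11
72.5,1.0,15.25,0.11
75.0,1.0,16.5,0.11
77.5,1.0,17.75,0.11
80.0,1.0,19.0,0.11
82.5,1.0,20.25,0.11
85.0,1.0,21.5,0.11
87.5,1.0,22.75,0.11
90.0,1.0,24.0,0.11
92.5,1.0,25.25,0.11
95.0,1.0,26.5,0.11
97.5,1.0,27.75,0.11
100.0,1.0,29.0,0.11
102.5,1.0,30.25,0.11
105.0,1.0,31.5,0.11
107.5,1.0,32.75,0.11
110.0,1.0,34.0,0.11
112.5,1.0,35.25,0.11
115.0,1.0,36.5,0.11
117.5,1.0,37.75,0.11
120.0,1.0,39.0,0.11
122.5,1.0,40.25,0.11
125.0,1.0,41.5,0.11
127.5,1.0,42.75,0.11
130.0,1.0,44.0,0.11
132.5,1.0,45.25,0.11
135.0,1.0,46.5,0.11
137.5,1.0,47.75,0.11
140.0,1.0,49.0,0.11
142.5,1.0,50.25,0.11
145.0,1.0,51.5,0.11
147.5,1.0,52.75,0.11
150.0,1.0,54.0,0.11
152.5,1.0,55.25,0.11
155.0,1.0,56.5,0.11
157.5,1.0,57.75,0.11
160.0,1.0,59.0,0.11
162.5,1.0,60.25,0.11
165.0,1.0,61.5,0.11
167.5,1.0,62.75,0.11
170.0,1.0,64.0,0.11
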