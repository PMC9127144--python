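index,x_deg,y_deg
0,5,5
1,-5,5
2,5,-5
3,-5,-5
4,15,5
5,-15,5
6,15,-5
7,-15,-5
8,25,5
9,-25,5
10,25,-5
11,-25,-5
12,35,5
13,-35,5
14,35,-5
15,-35,-5
16,45,5
17,-45,5
18,45,-5
19,-45,-5
20,55,5
21,-55,5
22,55,-5
23,-55,-5
24,65,5
25,-65,5
26,65,-5
27,-65,-5
28,75,5
29,-75,5
30,75,-5
31,-75,-5
32,5,15
33,-5,15
34,5,-15
35,-5,-15
36,15,15
37,-15,15
38,15,-15
39,-15,-15
40,25,15
41,-25,15
42,25,-15
43,-25,-15
44,35,15
45,-35,15
46,35,-15
47,-35,-15
48,45,15
49,-45,15
50,45,-15
51,-45,-15
52,55,15
53,-55,15
54,55,-15
55,-55,-15
56,65,15
57,-65,15
58,65,-15
59,-65,-15
60,75,15
61,-75,15
62,75,-15
63,-75,-15
64,5,25
65,-5,25
66,5,-25
67,-5,-25
68,15,25
69,-15,25
70,15,-25
71,-15,-25
72,25,25
73,-25,25
74,25,-25
75,-25,-25
76,35,25
77,-35,25
78,35,-25
79,-35,-25
80,45,25
81,-45,25
82,45,-25
83,-45,-25
84,55,25
85,-55,25
86,55,-25
87,-55,-25
88,65,25
89,-65,25
90,65,-25
91,-65,-25
92,75,25
93,-75,25
94,75,-25
95,-75,-25
96,5,35
97,-5,35
98,5,-35
99,-5,-35
100,15,35
101,-15,35
102,15,-35
103,-15,-35
104,25,35
105,-25,35
106,25,-35
107,-25,-35
108,35,35
109,-35,35
110,35,-35
111,-35,-35
112,45,35
113,-45,35
114,45,-35
115,-45,-35
116,55,35
117,-55,35
118,55,-35
119,-55,-35
120,65,35
121,-65,35
122,65,-35
123,-65,-35
124,5,45
125,-5,45
126,5,-45
127,-5,-45
128,15,45
129,-15,45
130,15,-45
131,-15,-45
132,25,45
133,-25,45
134,25,-45
135,-25,-45
136,35,45
137,-35,45
138,35,-45
139,-35,-45
140,45,45
141,-45,45
142,45,-45
143,-45,-45
144,55,45
145,-55,45
146,55,-45
147,-55,-45
148,5,55
149,-5,55
150,5,-55
151,-5,-55
152,15,55
153,-15,55
154,15,-55
155,-15,-55
156,25,55
157,-25,55
158,25,-55
159,-25,-55
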