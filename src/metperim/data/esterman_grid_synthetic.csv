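index,x_deg,y_deg
0,-15,30
1,15,30
2,-55,15
3,-40,15
4,-25,15
5,-10,15
6,10,15
7,25,15
8,40,15
9,55,15
10,-70,8
11,-55,8
12,-40,8
13,-28,8
14,-19,8
15,-12,8
16,-6,8
17,6,8
18,12,8
19,19,8
20,28,8
21,40,8
22,55,8
23,70,8
24,-75,3
25,-62,3
26,-50,3
27,-39,3
28,-29,3
29,-20,3
30,-13,3
31,-7,3
32,-2,3
33,2,3
34,7,3
35,13,3
36,20,3
37,29,3
38,39,3
39,50,3
40,62,3
41,75,3
42,-75,-3
43,-62,-3
44,-50,-3
45,-39,-3
46,-29,-3
47,-20,-3
48,-13,-3
49,-7,-3
50,-2,-3
51,2,-3
52,7,-3
53,13,-3
54,20,-3
55,29,-3
56,39,-3
57,50,-3
58,62,-3
59,75,-3
60,-70,-8
61,-55,-8
62,-40,-8
63,-28,-8
64,-19,-8
65,-12,-8
66,-6,-8
67,6,-8
68,12,-8
69,19,-8
70,28,-8
71,40,-8
72,55,-8
73,70,-8
74,-70,-15
75,-60,-15
76,-45,-15
77,-32,-15
78,-21,-15
79,-12,-15
80,-5,-15
81,5,-15
82,12,-15
83,21,-15
84,32,-15
85,45,-15
86,60,-15
87,70,-15
88,-65,-25
89,-55,-25
90,-40,-25
91,-27,-25
92,-16,-25
93,-7,-25
94,7,-25
95,16,-25
96,27,-25
97,40,-25
98,55,-25
99,65,-25
100,-58,-35
101,-45,-35
102,-30,-35
103,-18,-35
104,-8,-35
105,8,-35
106,18,-35
107,30,-35
108,45,-35
109,58,-35
110,-35,-45
111,-22,-45
112,-10,-45
113,10,-45
114,22,-45
115,35,-45
116,-20,-55
117,-7,-55
118,7,-55
119,20,-55
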