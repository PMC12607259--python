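parcel_id,label,hemisphere,partner_id,network
0,L_000,L,180,FPN
1,L_001,L,181,FPN
2,L_002,L,182,FPN
3,L_003,L,183,FPN
4,L_004,L,184,FPN
5,L_005,L,185,FPN
6,L_006,L,186,FPN
7,L_007,L,187,FPN
8,L_008,L,188,FPN
9,L_009,L,189,FPN
10,L_010,L,190,FPN
11,L_011,L,191,FPN
12,L_012,L,192,FPN
13,L_013,L,193,FPN
14,L_014,L,194,FPN
15,L_015,L,195,FPN
16,L_016,L,196,FPN
17,L_017,L,197,FPN
18,L_018,L,198,FPN
19,L_019,L,199,FPN
20,L_020,L,200,FPN
21,L_021,L,201,FPN
22,L_022,L,202,FPN
23,L_023,L,203,FPN
24,L_024,L,204,OTHER
25,L_025,L,205,OTHER
26,L_026,L,206,OTHER
27,L_027,L,207,OTHER
28,L_028,L,208,OTHER
29,L_029,L,209,OTHER
30,L_030,L,210,OTHER
31,L_031,L,211,OTHER
32,L_032,L,212,OTHER
33,L_033,L,213,OTHER
34,L_034,L,214,OTHER
35,L_035,L,215,OTHER
36,L_036,L,216,OTHER
37,L_037,L,217,OTHER
38,L_038,L,218,OTHER
39,L_039,L,219,OTHER
40,L_040,L,220,OTHER
41,L_041,L,221,OTHER
42,L_042,L,222,OTHER
43,L_043,L,223,OTHER
44,L_044,L,224,OTHER
45,L_045,L,225,OTHER
46,L_046,L,226,OTHER
47,L_047,L,227,OTHER
48,L_048,L,228,OTHER
49,L_049,L,229,OTHER
50,L_050,L,230,OTHER
51,L_051,L,231,OTHER
52,L_052,L,232,OTHER
53,L_053,L,233,OTHER
54,L_054,L,234,OTHER
55,L_055,L,235,OTHER
56,L_056,L,236,OTHER
57,L_057,L,237,OTHER
58,L_058,L,238,OTHER
59,L_059,L,239,OTHER
60,L_060,L,240,OTHER
61,L_061,L,241,OTHER
62,L_062,L,242,OTHER
63,L_063,L,243,OTHER
64,L_064,L,244,OTHER
65,L_065,L,245,OTHER
66,L_066,L,246,OTHER
67,L_067,L,247,OTHER
68,L_068,L,248,OTHER
69,L_069,L,249,OTHER
70,L_070,L,250,OTHER
71,L_071,L,251,OTHER
72,L_072,L,252,OTHER
73,L_073,L,253,OTHER
74,L_074,L,254,OTHER
75,L_075,L,255,OTHER
76,L_076,L,256,OTHER
77,L_077,L,257,OTHER
78,L_078,L,258,OTHER
79,L_079,L,259,OTHER
80,L_080,L,260,OTHER
81,L_081,L,261,OTHER
82,L_082,L,262,OTHER
83,L_083,L,263,OTHER
84,L_084,L,264,OTHER
85,L_085,L,265,OTHER
86,L_086,L,266,OTHER
87,L_087,L,267,OTHER
88,L_088,L,268,OTHER
89,L_089,L,269,OTHER
90,L_090,L,270,OTHER
91,L_091,L,271,OTHER
92,L_092,L,272,OTHER
93,L_093,L,273,OTHER
94,L_094,L,274,OTHER
95,L_095,L,275,OTHER
96,L_096,L,276,OTHER
97,L_097,L,277,OTHER
98,L_098,L,278,OTHER
99,L_099,L,279,OTHER
100,L_100,L,280,OTHER
101,L_101,L,281,OTHER
102,L_102,L,282,OTHER
103,L_103,L,283,OTHER
104,L_104,L,284,OTHER
105,L_105,L,285,OTHER
106,L_106,L,286,OTHER
107,L_107,L,287,OTHER
108,L_108,L,288,OTHER
109,L_109,L,289,OTHER
110,L_110,L,290,OTHER
111,L_111,L,291,OTHER
112,L_112,L,292,OTHER
113,L_113,L,293,OTHER
114,L_114,L,294,OTHER
115,L_115,L,295,OTHER
116,L_116,L,296,OTHER
117,L_117,L,297,OTHER
118,L_118,L,298,OTHER
119,L_119,L,299,OTHER
120,L_120,L,300,OTHER
121,L_121,L,301,OTHER
122,L_122,L,302,OTHER
123,L_123,L,303,OTHER
124,L_124,L,304,OTHER
125,L_125,L,305,OTHER
126,L_126,L,306,OTHER
127,L_127,L,307,OTHER
128,L_128,L,308,OTHER
129,L_129,L,309,OTHER
130,L_130,L,310,OTHER
131,L_131,L,311,OTHER
132,L_132,L,312,OTHER
133,L_133,L,313,OTHER
134,L_134,L,314,OTHER
135,L_135,L,315,OTHER
136,L_136,L,316,OTHER
137,L_137,L,317,OTHER
138,L_138,L,318,OTHER
139,L_139,L,319,OTHER
140,L_140,L,320,OTHER
141,L_141,L,321,OTHER
142,L_142,L,322,OTHER
143,L_143,L,323,OTHER
144,L_144,L,324,OTHER
145,L_145,L,325,OTHER
146,L_146,L,326,OTHER
147,L_147,L,327,OTHER
148,L_148,L,328,OTHER
149,L_149,L,329,OTHER
150,L_150,L,330,OTHER
151,L_151,L,331,OTHER
152,L_152,L,332,OTHER
153,L_153,L,333,OTHER
154,L_154,L,334,OTHER
155,L_155,L,335,OTHER
156,L_156,L,336,OTHER
157,L_157,L,337,OTHER
158,L_158,L,338,OTHER
159,L_159,L,339,OTHER
160,L_160,L,340,OTHER
161,L_161,L,341,OTHER
162,L_162,L,342,OTHER
163,L_163,L,343,OTHER
164,L_164,L,344,OTHER
165,L_165,L,345,OTHER
166,L_166,L,346,OTHER
167,L_167,L,347,OTHER
168,L_168,L,348,OTHER
169,L_169,L,349,OTHER
170,L_170,L,350,OTHER
171,L_171,L,351,OTHER
172,L_172,L,352,OTHER
173,L_173,L,353,OTHER
174,L_174,L,354,OTHER
175,L_175,L,355,OTHER
176,L_176,L,356,OTHER
177,L_177,L,357,OTHER
178,L_178,L,358,OTHER
179,L_179,L,359,OTHER
180,R_000,R,0,FPN
181,R_001,R,1,FPN
182,R_002,R,2,FPN
183,R_003,R,3,FPN
184,R_004,R,4,FPN
185,R_005,R,5,FPN
186,R_006,R,6,FPN
187,R_007,R,7,FPN
188,R_008,R,8,FPN
189,R_009,R,9,FPN
190,R_010,R,10,FPN
191,R_011,R,11,FPN
192,R_012,R,12,FPN
193,R_013,R,13,FPN
194,R_014,R,14,FPN
195,R_015,R,15,FPN
196,R_016,R,16,FPN
197,R_017,R,17,FPN
198,R_018,R,18,FPN
199,R_019,R,19,FPN
200,R_020,R,20,FPN
201,R_021,R,21,FPN
202,R_022,R,22,FPN
203,R_023,R,23,FPN
204,R_024,R,24,OTHER
205,R_025,R,25,OTHER
206,R_026,R,26,OTHER
207,R_027,R,27,OTHER
208,R_028,R,28,OTHER
209,R_029,R,29,OTHER
210,R_030,R,30,OTHER
211,R_031,R,31,OTHER
212,R_032,R,32,OTHER
213,R_033,R,33,OTHER
214,R_034,R,34,OTHER
215,R_035,R,35,OTHER
216,R_036,R,36,OTHER
217,R_037,R,37,OTHER
218,R_038,R,38,OTHER
219,R_039,R,39,OTHER
220,R_040,R,40,OTHER
221,R_041,R,41,OTHER
222,R_042,R,42,OTHER
223,R_043,R,43,OTHER
224,R_044,R,44,OTHER
225,R_045,R,45,OTHER
226,R_046,R,46,OTHER
227,R_047,R,47,OTHER
228,R_048,R,48,OTHER
229,R_049,R,49,OTHER
230,R_050,R,50,OTHER
231,R_051,R,51,OTHER
232,R_052,R,52,OTHER
233,R_053,R,53,OTHER
234,R_054,R,54,OTHER
235,R_055,R,55,OTHER
236,R_056,R,56,OTHER
237,R_057,R,57,OTHER
238,R_058,R,58,OTHER
239,R_059,R,59,OTHER
240,R_060,R,60,OTHER
241,R_061,R,61,OTHER
242,R_062,R,62,OTHER
243,R_063,R,63,OTHER
244,R_064,R,64,OTHER
245,R_065,R,65,OTHER
246,R_066,R,66,OTHER
247,R_067,R,67,OTHER
248,R_068,R,68,OTHER
249,R_069,R,69,OTHER
250,R_070,R,70,OTHER
251,R_071,R,71,OTHER
252,R_072,R,72,OTHER
253,R_073,R,73,OTHER
254,R_074,R,74,OTHER
255,R_075,R,75,OTHER
256,R_076,R,76,OTHER
257,R_077,R,77,OTHER
258,R_078,R,78,OTHER
259,R_079,R,79,OTHER
260,R_080,R,80,OTHER
261,R_081,R,81,OTHER
262,R_082,R,82,OTHER
263,R_083,R,83,OTHER
264,R_084,R,84,OTHER
265,R_085,R,85,OTHER
266,R_086,R,86,OTHER
267,R_087,R,87,OTHER
268,R_088,R,88,OTHER
269,R_089,R,89,OTHER
270,R_090,R,90,OTHER
271,R_091,R,91,OTHER
272,R_092,R,92,OTHER
273,R_093,R,93,OTHER
274,R_094,R,94,OTHER
275,R_095,R,95,OTHER
276,R_096,R,96,OTHER
277,R_097,R,97,OTHER
278,R_098,R,98,OTHER
279,R_099,R,99,OTHER
280,R_100,R,100,OTHER
281,R_101,R,101,OTHER
282,R_102,R,102,OTHER
283,R_103,R,103,OTHER
284,R_104,R,104,OTHER
285,R_105,R,105,OTHER
286,R_106,R,106,OTHER
287,R_107,R,107,OTHER
288,R_108,R,108,OTHER
289,R_109,R,109,OTHER
290,R_110,R,110,OTHER
291,R_111,R,111,OTHER
292,R_112,R,112,OTHER
293,R_113,R,113,OTHER
294,R_114,R,114,OTHER
295,R_115,R,115,OTHER
296,R_116,R,116,OTHER
297,R_117,R,117,OTHER
298,R_118,R,118,OTHER
299,R_119,R,119,OTHER
300,R_120,R,120,OTHER
301,R_121,R,121,OTHER
302,R_122,R,122,OTHER
303,R_123,R,123,OTHER
304,R_124,R,124,OTHER
305,R_125,R,125,OTHER
306,R_126,R,126,OTHER
307,R_127,R,127,OTHER
308,R_128,R,128,OTHER
309,R_129,R,129,OTHER
310,R_130,R,130,OTHER
311,R_131,R,131,OTHER
312,R_132,R,132,OTHER
313,R_133,R,133,OTHER
314,R_134,R,134,OTHER
315,R_135,R,135,OTHER
316,R_136,R,136,OTHER
317,R_137,R,137,OTHER
318,R_138,R,138,OTHER
319,R_139,R,139,OTHER
320,R_140,R,140,OTHER
321,R_141,R,141,OTHER
322,R_142,R,142,OTHER
323,R_143,R,143,OTHER
324,R_144,R,144,OTHER
325,R_145,R,145,OTHER
326,R_146,R,146,OTHER
327,R_147,R,147,OTHER
328,R_148,R,148,OTHER
329,R_149,R,149,OTHER
330,R_150,R,150,OTHER
331,R_151,R,151,OTHER
332,R_152,R,152,OTHER
333,R_153,R,153,OTHER
334,R_154,R,154,OTHER
335,R_155,R,155,OTHER
336,R_156,R,156,OTHER
337,R_157,R,157,OTHER
338,R_158,R,158,OTHER
339,R_159,R,159,OTHER
340,R_160,R,160,OTHER
341,R_161,R,161,OTHER
342,R_162,R,162,OTHER
343,R_163,R,163,OTHER
344,R_164,R,164,OTHER
345,R_165,R,165,OTHER
346,R_166,R,166,OTHER
347,R_167,R,167,OTHER
348,R_168,R,168,OTHER
349,R_169,R,169,OTHER
350,R_170,R,170,OTHER
351,R_171,R,171,OTHER
352,R_172,R,172,OTHER
353,R_173,R,173,OTHER
354,R_174,R,174,OTHER
355,R_175,R,175,OTHER
356,R_176,R,176,OTHER
357,R_177,R,177,OTHER
358,R_178,R,178,OTHER
359,R_179,R,179,OTHER
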