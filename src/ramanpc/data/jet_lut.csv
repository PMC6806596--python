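R,G,B
0,0,128
0,0,132
0,0,136
0,0,140
0,0,144
0,0,147
0,0,152
0,0,156
0,0,160
0,0,163
0,0,168
0,0,172
0,0,176
0,0,179
0,0,184
0,0,188
0,0,192
0,0,195
0,0,200
0,0,204
0,0,208
0,0,211
0,0,216
0,0,220
0,0,224
0,0,227
0,0,232
0,0,236
0,0,240
0,0,243
0,0,248
0,0,252
0,0,255
0,5,255
0,8,255
0,13,255
0,16,255
0,21,255
0,24,255
0,29,255
0,32,255
0,37,255
0,40,255
0,45,255
0,48,255
0,53,255
0,56,255
0,61,255
0,64,255
0,69,255
0,72,255
0,77,255
0,80,255
0,85,255
0,88,255
0,93,255
0,96,255
0,101,255
0,104,255
0,109,255
0,112,255
0,117,255
0,120,255
0,125,255
0,128,255
0,132,255
0,137,255
0,140,255
0,144,255
0,148,255
0,153,255
0,156,255
0,160,255
0,164,255
0,169,255
0,172,255
0,176,255
0,180,255
0,185,255
0,188,255
0,192,255
0,196,255
0,201,255
0,204,255
0,208,255
0,212,255
0,217,255
0,220,255
0,224,255
0,228,255
0,233,255
0,236,255
0,240,255
0,244,255
0,249,255
0,252,255
1,255,254
5,255,250
10,255,245
14,255,242
17,255,238
21,255,234
26,255,229
30,255,226
33,255,222
37,255,218
42,255,213
46,255,210
49,255,206
53,255,202
58,255,197
62,255,194
66,255,190
69,255,186
74,255,181
78,255,178
82,255,174
85,255,170
90,255,165
94,255,162
98,255,158
101,255,154
106,255,149
110,255,146
114,255,142
117,255,138
122,255,133
126,255,130
130,255,126
133,255,122
137,255,118
141,255,114
146,255,109
150,255,105
154,255,101
158,255,98
162,255,94
165,255,90
169,255,86
173,255,82
178,255,77
182,255,73
186,255,69
190,255,66
194,255,62
197,255,58
201,255,54
205,255,50
210,255,45
214,255,41
218,255,37
222,255,33
226,255,30
229,255,26
233,255,22
237,255,18
242,255,13
246,255,9
250,255,5
254,255,1
255,252,0
255,249,0
255,245,0
255,241,0
255,236,0
255,232,0
255,228,0
255,224,0
255,220,0
255,217,0
255,213,0
255,209,0
255,204,0
255,200,0
255,196,0
255,192,0
255,188,0
255,185,0
255,181,0
255,177,0
255,172,0
255,168,0
255,164,0
255,160,0
255,156,0
255,153,0
255,149,0
255,145,0
255,140,0
255,136,0
255,132,0
255,128,0
255,125,0
255,121,0
255,117,0
255,113,0
255,108,0
255,104,0
255,100,0
255,96,0
255,93,0
255,89,0
255,85,0
255,81,0
255,76,0
255,72,0
255,68,0
255,64,0
255,61,0
255,57,0
255,53,0
255,49,0
255,44,0
255,40,0
255,36,0
255,32,0
255,29,0
255,25,0
255,21,0
255,17,0
255,12,0
255,8,0
255,4,0
255,0,0
252,0,0
248,0,0
244,0,0
240,0,0
235,0,0
231,0,0
227,0,0
224,0,0
220,0,0
216,0,0
212,0,0
208,0,0
203,0,0
199,0,0
195,0,0
192,0,0
188,0,0
184,0,0
180,0,0
176,0,0
171,0,0
167,0,0
163,0,0
160,0,0
156,0,0
152,0,0
148,0,0
144,0,0
139,0,0
135,0,0
132,0,0
128,0,0
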