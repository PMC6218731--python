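case,normotensive,hypertensive,hypotensive,bad_quality,missing_reference,total
1,581,0,64,419,376,1440
2,12,0,14,166,0,192
3,1099,0,50,1400,1051,3600
4,496,0,0,649,295,1440
5,50,32,0,352,1726,2160
6,357,56,69,158,80,720
7,128,0,56,289,247,720
8,248,0,0,296,152,696
9,465,0,0,178,77,720
10,44,1,0,195,0,240
11,395,51,71,203,0,720
12,312,0,392,468,268,1440
13,324,0,8,223,165,720
14,0,0,61,95,0,156
15,0,0,12,158,0,170
16,0,0,46,86,28,160
17,65,0,4,70,27,166
18,81,0,0,81,0,162
19,40,15,0,84,20,159
20,286,3,11,256,164,720
21,101,0,59,119,81,360
22,56,52,11,167,74,360
23,22,76,0,226,0,324
24,20,0,0,160,0,180
25,101,57,19,468,75,720
26,152,21,7,367,173,720
27,98,0,0,388,101,720
28,231,0,0,403,79,720
29,211,0,27,480,0,720
30,48,0,0,84,0,132
31,315,72,34,798,221,1440
32,144,200,0,286,90,720
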