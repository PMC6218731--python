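case,normo_ref,normo_est,normo_diff,hyper_ref,hyper_est,hyper_diff,hypo_ref,hypo_est,hypo_diff
1,98.0,97.6,0.4,,,,85.7,92.4,-6.7
2,120.2,108.2,12.1,,,,85.1,115.7,-30.6
3,99.5,100.7,-1.1,,,,80.2,99.1,-18.9
4,107.6,108.2,-0.6,,,,,,
5,121.8,120.4,1.4,188.7,185.6,3.2,,,
6,108.5,104.5,4.0,188.9,155.4,33.5,84.2,93.2,-9.0
7,97.3,101.6,-4.3,,,,87.6,90.7,-3.1
8,104.4,105.9,-1.5,,,,,,
9,105.7,103.2,2.4,,,,,,
10,117.7,107.0,10.7,104.0,104.0,0.0,,,
11,111.1,110.2,1.0,131.9,130.6,1.3,87.7,100.5,-12.8
12,103.0,103.3,-0.3,,,,78.9,85.7,-6.8
13,101.7,102.2,-0.6,,,,84.0,86.5,-2.5
14,,,,,,,84.8,87.0,-2.1
15,,,,,,,84.6,88.2,-3.6
16,,,,,,,85.0,86.6,-1.6
17,93.6,103.9,-10.3,,,,82.5,124.4,-41.9
18,113.7,117.1,-3.4,,,,,,
19,106.3,115.9,-9.6,145.0,117.3,27.8,,,
20,116.0,115.8,0.2,144.0,105.9,38.1,87.0,116.0,-29.0
21,99.9,106.3,-6.4,,,,85.0,97.8,-12.8
22,116.0,111.6,4.4,150.4,124.9,25.5,87.0,117.4,-30.4
23,123.2,134.1,-11.0,155.7,131.8,23.9,,,
24,95.0,97.7,-2.7,,,,,,
25,119.5,120.2,-0.7,147.8,127.7,20.1,83.7,125.9,-42.1
26,117.0,114.9,2.0,162.0,124.3,37.7,87.0,109.5,-22.5
27,124.0,118.6,5.4,,,,,,
28,106.3,115.2,-8.9,135.5,121.2,14.3,,,
29,105.7,102.9,2.8,,,,83.8,91.8,-8.0
30,108.0,118.3,-10.3,,,,,,
31,114.9,118.5,-3.6,147.0,125.0,22.0,85.2,105.7,-20.5
32,118.7,122.7,-4.0,171.6,146.0,25.6,,,
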