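case,sbp_ref,sbp_est,sbp_diff,dbp_ref,dbp_est,dbp_diff
1,96.8,97.1,-0.3,49.1,49.1,0.0
2,102.1,112.0,-9.9,43.2,64.7,-21.5
3,98.7,100.7,-1.9,53.1,53.1,0.0
4,107.5,108.1,-0.6,58.2,58.6,-0.3
5,139.6,135.7,4.0,71.8,69.3,2.5
6,112.3,108.3,4.1,58.4,56.7,1.7
7,91.5,96.3,-4.8,44.4,46.8,-2.5
8,103.6,105.3,-1.8,52.1,53.1,-1.0
9,103.0,100.7,2.4,46.0,46.0,-0.1
10,118.4,107.1,11.3,51.8,50.5,1.3
11,109.9,111.0,-1.1,67.4,66.0,1.4
12,89.6,93.5,-3.9,53.0,53.2,-0.2
13,101.2,101.8,-0.6,64.4,61.5,2.9
14,84.8,86.9,-2.1,56.7,56.4,0.3
15,84.5,87.6,-3.1,49.6,52.4,-2.8
16,85.0,86.6,-1.6,56.2,57.3,-1.1
17,92.9,105.1,-12.1,57.5,59.4,-1.9
18,113.6,117.7,-4.1,59.3,62.6,-3.2
19,116.9,116.3,0.6,58.1,63.9,-5.8
20,115.2,115.7,-0.6,59.8,62.8,-3.0
21,94.4,103.0,-8.6,45.4,51.2,-5.7
22,128.3,117.7,10.7,59.7,60.1,-0.4
23,148.4,132.4,16.1,80.5,71.1,9.4
24,95.0,100.0,-5.0,61.4,70.1,-8.7
25,124.2,123.1,1.0,65.8,63.6,2.1
26,121.3,116.1,5.2,59.0,60.5,-1.6
27,124.0,118.6,5.4,71.1,68.2,2.8
28,108.3,115.0,-6.7,59.6,62.4,-2.8
29,103.2,101.6,1.6,61.3,60.3,1.0
30,108.0,118.3,-10.3,71.1,63.3,7.8
31,118.0,118.7,-0.7,72.3,69.8,2.5
32,147.2,135.1,12.0,77.4,71.6,5.8
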