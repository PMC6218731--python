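case,normo_ref,normo_est,normo_diff,hyper_ref,hyper_est,hyper_diff,hypo_ref,hypo_est,hypo_diff
1,49.8,49.3,0.5,,,,45.7,46.8,-1.0
2,43.0,64.3,-21.3,,,,44.0,65.1,-21.1
3,54.5,53.3,1.2,,,,48.4,50.0,-1.6
4,59.0,58.5,0.5,,,,,,
5,67.0,65.6,1.4,79.1,79.1,0.0,,,
6,60.5,57.2,3.3,88.0,74.0,14.0,41.6,46.8,-5.2
7,49.3,48.4,0.9,,,,43.1,45.6,-2.5
8,53.0,53.5,-0.5,,,,,,
9,49.3,48.2,1.1,,,,,,
10,51.9,49.9,2.0,54.7,54.7,0.0,,,
11,69.9,66.3,3.6,93.0,80.3,12.7,49.2,54.3,-5.0
12,63.2,60.2,3.0,,,,46.7,47.7,-1.0
13,64.6,61.5,3.0,,,,56.0,60.2,-4.2
14,,,,,,,57.6,56.7,0.9
15,,,,,,,54.3,54.3,0.1
16,,,,,,,56.2,57.3,-1.1
17,58.3,59.8,-1.6,,,,45.5,52.8,-7.3
18,59.7,62.2,-2.5,,,,,,
19,51.6,64.6,-13.0,77.0,60.9,16.1,,,
20,60.3,62.5,-2.2,76.0,77.4,-1.4,50.0,65.8,-15.8
21,45.4,51.6,-6.2,,,,45.7,50.6,-4.9
22,63.1,58.9,4.2,62.5,61.3,1.2,40.0,62.5,-22.5
23,74.1,69.1,5.0,82.3,71.7,10.6,,,
24,61.5,67.3,-5.8,,,,,,
25,63.9,62.0,1.9,73.2,66.1,7.1,51.7,63.0,-11.3
26,57.4,60.2,-2.8,75.0,60.2,14.8,53.0,67.0,-14.0
27,71.1,68.2,2.8,,,,,,
28,60.7,63.2,-2.5,87.5,72.3,15.2,,,
29,65.8,61.7,4.1,,,,52.3,57.5,-5.2
30,71.1,63.3,7.8,,,,,,
31,70.8,68.5,2.3,87.4,76.0,11.5,57.4,68.3,-10.9
32,66.6,65.5,1.1,88.0,76.8,11.2,,,
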