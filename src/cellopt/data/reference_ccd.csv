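label,x1_coded,x2_coded,x3_coded,efficiency,sd,ann_fitted,role
1,-1.00,-1.00,-1.00,76.29,5.25,77.69,training
2,1.00,-1.00,-1.00,46.53,3.14,46.85,training
3,-1.00,1.00,-1.00,45.64,3.52,45.53,training
4,1.00,1.00,-1.00,67.12,4.94,68.28,training
5,-1.00,-1.00,1.00,59.45,4.15,59.58,training
6,1.00,-1.00,1.00,48.80,3.88,49.40,training
7,-1.00,1.00,1.00,61.89,4.68,64.31,training
8,1.00,1.00,1.00,73.77,5.01,74.10,training
9,-1.68,0.00,0.00,54.74,4.21,52.89,training
10,1.68,0.00,0.00,64.84,4.52,63.87,training
11,0.00,-1.68,0.00,45.73,3.57,47.18,training
12,0.00,1.68,0.00,63.49,4.36,62.75,training
13,0.00,0.00,-1.68,55.12,3.89,54.17,training
14,0.00,0.00,1.68,48.25,3.31,48.00,training
15,0.00,0.00,0.00,77.01,5.15,76.86,training
16,0.00,0.00,0.00,77.33,5.07,76.86,training
17,0.00,0.00,0.00,77.22,5.20,76.86,training
18,0.00,0.00,0.00,77.06,5.19,76.86,training
19,0.00,0.00,0.00,77.30,5.09,76.86,training
20,0.00,0.00,0.00,77.28,5.08,76.86,training
21,-1.68,0.00,1.00,76.22,4.77,78.17,validation
22,-1.00,1.00,0.00,71.31,3.98,69.38,validation
23,0.00,1.68,1.68,57.59,2.56,56.87,validation
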