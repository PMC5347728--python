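case,case_id,fish_cn,fish_class,mip_cn,mip_class,nac_ratio,nac_class
1,2,4.1,equivocal,4.00,equivocal,0.55,negative
2,3,22.9,positive,11.67,positive,3.13,positive
3,4,16.4,positive,11.00,positive,3.28,positive
4,6,18.5,positive,11.67,positive,4.22,positive
5,7,2.0,negative,2.00,negative,0.48,negative
6,8,1.9,negative,2.00,negative,0.50,negative
7,9,2.1,negative,2.00,negative,0.49,negative
8,10,2.0,negative,2.00,negative,0.37,negative
9,11,3.7,negative,3.00,negative,0.97,negative
10,12,1.9,negative,1.67,negative,0.36,negative
11,13,2.9,negative,2.00,negative,0.59,negative
12,15,7.6,positive,6.00,positive,0.88,negative
13,16,11.2,positive,8.00,positive,1.12,negative
14,17,19.9,positive,7.67,positive,2.44,positive
15,18,11.5,positive,14.00,positive,2.29,positive
16,19,24.6,positive,10.33,positive,3.42,positive
17,22,2.5,negative,3.00,negative,0.52,negative
18,23,4.1,equivocal,5.00,equivocal,0.81,negative
19,24,2.0,negative,2.00,negative,0.37,negative
20,25,2.4,negative,2.33,negative,0.57,negative
21,26,3.7,negative,2.70,negative,0.63,negative
22,27,3.7,negative,4.00,equivocal,0.85,negative
23,28,2.1,negative,2.00,negative,0.33,negative
24,29,2.8,negative,2.50,negative,0.52,negative
25,30,1.6,negative,1.00,negative,0.34,negative
26,31,2.1,negative,2.00,negative,0.36,negative
27,32,4.9,equivocal,7.00,positive,0.73,negative
28,33,2.2,negative,2.00,negative,0.33,negative
29,34,2.8,negative,2.00,negative,0.36,negative
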