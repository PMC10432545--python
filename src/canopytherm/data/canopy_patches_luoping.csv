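patch_no,area_hm2,perimeter_km,shape_index,cooling_rate_pct
1,65.32,25.17,8.79,4.60
2,64.54,32.29,11.34,6.22
3,56.18,13.73,5.17,6.75
4,45.24,25.18,10.56,5.06
5,18.60,4.70,3.07,6.39
6,18.12,14.53,9.63,7.58
7,16.47,6.29,4.37,7.81
8,10.95,4.90,4.18,−3.81
9,10.14,6.56,5.81,10.33
10,8.94,5.43,5.12,8.61
11,8.20,7.57,7.46,1.59
12,7.16,4.76,5.02,−3.57
13,6.71,4.58,4.99,−2.38
14,6.39,3.39,3.78,7.41
15,6.00,4.65,5.35,0.63
16,4.80,2.45,3.16,−4.17
17,4.70,3.83,4.98,5.69
18,3.49,6.67,10.06,0.63
19,3.38,2.15,3.29,−0.63
20,3.38,3.25,4.99,3.74
21,3.17,3.53,5.59,6.75
22,3.13,3.29,5.25,0.70
23,3.07,2.35,3.78,−8.18
24,2.74,1.92,3.26,−0.53
25,2.60,2.10,3.67,1.42
26,2.43,2.32,4.21,4.87
27,2.39,3.63,6.62,1.75
28,2.39,2.68,4.90,−2.58
29,2.23,3.88,7.33,−7.38
30,2.22,1.37,2.60,1.52
31,2.10,2.20,4.28,0.30
32,2.00,1.90,3.80,2.75
33,1.99,2.08,4.16,0.43
34,1.94,1.31,2.65,6.02
35,1.92,1.51,3.08,8.14
36,1.70,1.31,2.82,−2.38
37,1.68,2.75,5.99,−3.11
38,1.61,1.05,2.32,−0.03
39,1.56,1.12,2.53,−1.85
40,1.55,1.78,4.03,−0.23
41,1.53,1.53,3.49,−6.69
42,1.53,1.32,3.00,−0.86
43,1.48,2.50,5.78,2.68
44,1.46,1.41,3.29,−10.86
45,1.41,1.24,2.94,−0.30
46,1.34,1.10,2.69,3.44
47,1.31,1.65,4.05,6.98
48,1.27,0.78,1.94,−6.09
49,1.21,2.18,5.59,1.62
50,1.21,2.28,5.86,0.50
51,1.20,1.40,3.59,−5.10
52,1.19,1.98,5.13,−3.05
53,1.17,1.16,3.03,5.16
54,1.17,2.60,6.78,−7.41
55,1.16,2.49,6.54,−0.70
56,1.13,2.64,7.01,5.43
57,1.13,1.02,2.71,5.10
58,1.09,0.84,2.26,−0.89
59,1.06,1.63,4.48,0.10
60,1.05,1.38,3.80,6.52
61,1.05,1.56,4.29,−2.28
62,1.01,0.98,2.74,6.55
63,1.01,0.84,2.37,−15.33
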