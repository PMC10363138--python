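specimen,reduction_mb,reduction_db,reduction_ml,reduction_dl,toc_md,toc_bl,margin_width
1,1.09,1.28,1.65,1.40,25.03,9.81,0.38
2,1.65,2.03,2.10,1.74,39.21,40.39,0.33
3,1.32,1.75,1.59,1.52,27.89,10.52,0.42
4,1.93,1.92,2.70,1.92,25.92,21.76,0.26
5,1.59,1.76,1.66,1.72,29.51,21.89,0.31
6,1.19,1.67,1.77,1.84,35.52,27.02,0.29
7,2.12,2.62,2.04,1.61,39.11,31.25,0.38
8,1.31,1.57,2.18,1.68,26.00,14.09,0.34
9,1.42,1.65,1.67,1.51,31.47,13.32,0.37
10,1.00,1.64,1.63,1.16,34.71,27.10,0.45
11,1.25,1.42,1.41,1.24,33.70,14.05,0.32
12,1.18,0.98,1.67,1.52,25.31,13.97,0.46
13,1.14,1.30,2.16,1.60,19.02,24.57,0.26
14,1.02,1.07,1.61,1.01,23.29,9.36,0.35
15,1.59,2.18,1.32,1.04,22.42,15.54,0.42
16,1.65,1.70,2.55,2.22,21.25,17.06,0.55
17,1.49,2.10,2.49,1.99,28.96,19.02,0.28
18,1.35,1.31,2.06,1.39,21.84,14.08,0.18
19,1.35,1.22,2.19,1.93,19.70,17.09,0.51
20,1.67,1.70,2.26,1.87,31.29,12.68,0.24
21,1.03,1.21,1.53,1.25,19.74,22.71,0.40
22,1.06,1.16,1.51,1.72,23.96,25.79,0.31
23,1.23,1.53,1.70,1.61,22.25,0.79,0.36
24,0.61,0.86,1.92,1.42,18.12,3.55,0.42
25,1.51,1.83,2.14,1.62,23.90,19.31,0.37
26,1.04,1.38,1.46,1.40,30.26,28.30,0.36
27,1.61,1.95,1.91,1.82,33.83,30.04,0.40
28,0.97,0.64,1.16,0.73,23.43,17.80,0.23
29,1.41,1.37,1.65,1.58,12.84,20.41,0.32
30,1.19,1.45,1.45,1.41,23.45,11.98,0.30
31,1.82,2.09,2.09,1.66,25.07,25.20,0.30
32,2.21,2.26,2.24,1.79,31.45,30.89,0.39
33,1.74,1.85,2.65,2.35,18.69,38.33,0.63
34,2.07,2.19,2.26,2.13,22.27,11.24,0.28
35,0.81,1.09,1.36,1.15,34.68,14.25,0.41
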