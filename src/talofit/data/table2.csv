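case_id,side,sex,H1,H2,H3,H4,H5,H6,H7,H8,H9
1,,,5.84,5.26,5.15,5.35,4.29,4.18,7.67,6.49,8.06
2,,,6.06,9.27,8.36,2.8,3.44,3.55,4.57,2.39,5.74
3,,,8.35,5.44,8.63,10.55,3.51,4.26,5.42,4.09,4.83
4,,,5.25,5.86,4.87,3.96,3.33,3.56,6.95,7.88,4.31
5,,,8.29,8.16,7.18,5.32,7.08,3.71,8.99,7.3,5.35
6,,,9.68,5.95,5.80,9.44,3.98,4.03,7.94,4.19,4.22
7,,,2.72,3.65,7.25,2.48,4.18,3.18,3.36,4.91,4.42
8,,,4.47,3.92,3.17,4.89,4.35,8.4,7.04,6.19,6.85
9,,,7.31,7.69,6.85,5.29,3.49,4.35,3.09,3.39,4.67
10,,,2.74,4.64,2.86,3.82,2.69,3.16,6.76,5.18,8.22
11,,,7.81,6.96,6.95,2.91,2.79,4.87,3.88,6.68,6.9
12,,,14.52,9.96,8.4,7.68,4.76,2.74,3.65,6.01,4.54
13,,,8.58,6.73,6.19,9.81,4.56,7.07,6.92,2.41,3.22
14,,,8.05,8.28,8.65,6.44,3.8,4.77,9.00,8.19,8.17
15,,,5.96,6.32,4.01,6.45,3.66,6.74,11.78,12.14,7.91
16,,,9.09,8.9,9.07,4.12,4.52,3.81,4.66,7.19,4.74
17,,,5.7,8.16,7.34,2.06,2.03,2.41,6.84,7.68,10.47
18,,,9.38,14.92,10,4.95,3.28,2.1,2.26,2.66,1.94
19,,,12.25,10.36,9.04,4.76,4.36,6.63,1.84,3.75,2.24
20,,,7.31,4.76,2.11,4.81,4.62,2.65,4.65,7.69,5.18
21,,,9.95,0,3.91,3.57,4.99,4.09,5.00,4.99,6.92
22,,,5.46,6.74,4.39,3.04,3.58,2.36,6.48,6.41,9.55
23,,,7.95,4.88,3.07,1.67,1.97,1.6,3.67,7.04,5.8
24,,,2.23,1.34,5.25,3.42,2.19,2.15,5.72,4.25,4.02
25,,,6.55,8.5,4.99,2.29,2.6,1.99,8.42,2.07,1.88
26,,,3.82,5.26,5.72,3.9,4.65,2.97,4.71,7.39,7.23
27,,,3.78,4.41,3.78,2.57,2.24,1.27,5.87,2.00,1.07
28,,,5.1,3.94,4.68,4.43,2.43,1.96,11.81,7.56,8.8
29,,,4.87,4.22,3.71,6.8,3.77,3.39,6.02,4.95,2.76
30,,,6.35,7.85,6.84,4.93,4.6,5.06,8.08,5.43,4.88
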