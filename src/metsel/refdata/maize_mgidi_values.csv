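hybrid,optimal,drought,waterlogging
1,4.83,5.58,5.33
2,4.12,5.92,7.23
3,5.21,4.66,5.71
4,5.62,5.51,4.53
5,5.00,7.01,6.64
6,3.81,5.10,5.13
7,5.54,6.08,5.66
8,4.06,4.59,3.48
9,6.09,3.82,4.58
10,5.31,5.53,5.53
11,6.43,5.96,5.50
12,5.07,5.21,6.42
13,5.44,5.28,3.33
14,2.91,3.68,3.13
15,6.24,4.53,6.24
16,5.11,5.22,5.49
17,5.46,4.40,5.26
18,4.98,4.60,5.97
19,3.85,3.06,3.39
20,5.27,5.66,5.51
21,5.58,5.07,4.86
22,3.25,2.49,3.43
23,5.77,6.14,5.54
24,6.89,4.65,5.79
25,5.16,4.82,4.87
26,2.97,4.54,4.66
27,5.78,5.59,5.33
28,5.88,6.08,4.50
29,5.45,4.94,5.46
30,3.04,4.10,3.22
31,5.10,4.39,4.65
32,7.15,6.50,5.46
33,5.42,6.38,6.52
34,5.23,5.01,5.96
35,5.22,5.20,5.92
36,3.79,7.04,4.45
37,5.17,3.72,4.46
38,5.73,4.91,5.92
39,4.68,5.21,4.90
40,4.98,4.95,5.62
41,3.88,3.13,4.59
42,4.65,4.09,4.94
43,4.64,6.45,5.52
44,3.57,2.98,4.37
45,4.99,5.65,5.11
46,4.94,4.01,5.56
47,4.79,5.56,4.87
48,4.07,5.23,5.98
49,3.64,4.92,2.95
50,5.02,3.63,4.46
51,4.95,5.95,5.61
52,6.26,6.28,6.69
53,4.33,3.87,5.56
54,5.91,5.27,5.76
55,5.20,4.51,4.23
56,5.94,5.15,5.09
57,6.54,7.03,6.59
58,3.45,5.45,4.14
59,3.76,4.92,4.26
60,3.34,5.16,4.05
61,5.73,4.40,4.32
62,6.38,5.01,5.59
63,5.21,5.78,6.19
64,3.67,4.44,4.16
65,5.92,6.89,5.63
66,4.93,5.54,5.32
67,5.20,5.65,5.41
68,5.63,6.79,5.74
69,4.67,6.44,5.40
70,5.67,5.46,5.89
71,3.98,5.72,4.56
72,4.96,4.31,4.41
73,4.16,4.12,4.75
74,4.60,3.33,4.66
75,4.24,5.07,4.10
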