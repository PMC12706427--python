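ID,TIME,DV,AMT,EVID,WT,SEX
1,0.0,.,319.99,1,79.6,0
1,0.25,2.84,.,0,79.6,0
1,0.57,6.57,.,0,79.6,0
1,1.12,10.5,.,0,79.6,0
1,2.02,9.66,.,0,79.6,0
1,3.82,8.58,.,0,79.6,0
1,5.1,8.36,.,0,79.6,0
1,7.03,7.47,.,0,79.6,0
1,9.05,6.89,.,0,79.6,0
1,12.12,5.94,.,0,79.6,0
1,24.37,3.28,.,0,79.6,0
2,0.0,.,318.56,1,72.4,1
2,0.27,1.72,.,0,72.4,1
2,0.52,7.91,.,0,72.4,1
2,1.0,8.31,.,0,72.4,1
2,1.92,8.33,.,0,72.4,1
2,3.5,6.85,.,0,72.4,1
2,5.02,6.08,.,0,72.4,1
2,7.03,5.4,.,0,72.4,1
2,9.0,4.55,.,0,72.4,1
2,12.0,3.01,.,0,72.4,1
2,24.3,0.9,.,0,72.4,1
3,0.0,.,319.36,1,70.5,0
3,0.27,4.4,.,0,70.5,0
3,0.58,6.9,.,0,70.5,0
3,1.02,8.2,.,0,70.5,0
3,2.02,7.8,.,0,70.5,0
3,3.62,7.5,.,0,70.5,0
3,5.08,6.2,.,0,70.5,0
3,7.07,5.3,.,0,70.5,0
3,9.0,4.9,.,0,70.5,0
3,12.15,3.7,.,0,70.5,0
3,24.17,1.05,.,0,70.5,0
4,0.0,.,319.88,1,72.7,1
4,0.35,1.89,.,0,72.7,1
4,0.6,4.6,.,0,72.7,1
4,1.07,8.6,.,0,72.7,1
4,2.13,8.38,.,0,72.7,1
4,3.5,7.54,.,0,72.7,1
4,5.02,6.88,.,0,72.7,1
4,7.02,5.78,.,0,72.7,1
4,9.02,5.33,.,0,72.7,1
4,11.98,4.19,.,0,72.7,1
4,24.65,1.15,.,0,72.7,1
5,0.0,.,319.96,1,54.6,0
5,0.3,2.02,.,0,54.6,0
5,0.52,5.63,.,0,54.6,0
5,1.0,11.4,.,0,54.6,0
5,2.02,9.33,.,0,54.6,0
5,3.5,8.74,.,0,54.6,0
5,5.02,7.56,.,0,54.6,0
5,7.02,7.09,.,0,54.6,0
5,9.1,5.9,.,0,54.6,0
5,12.0,4.37,.,0,54.6,0
5,24.35,1.57,.,0,54.6,0
6,0.0,.,320.0,1,80.0,1
6,0.27,1.29,.,0,80.0,1
6,0.58,3.08,.,0,80.0,1
6,1.15,6.44,.,0,80.0,1
6,2.03,6.32,.,0,80.0,1
6,3.57,5.53,.,0,80.0,1
6,5.0,4.94,.,0,80.0,1
6,7.0,4.02,.,0,80.0,1
6,9.22,3.46,.,0,80.0,1
6,12.1,2.78,.,0,80.0,1
6,23.85,0.92,.,0,80.0,1
7,0.0,.,319.77,1,64.6,0
7,0.25,0.85,.,0,64.6,0
7,0.5,2.35,.,0,64.6,0
7,1.02,5.02,.,0,64.6,0
7,2.02,6.58,.,0,64.6,0
7,3.48,7.09,.,0,64.6,0
7,5.0,6.66,.,0,64.6,0
7,6.98,5.25,.,0,64.6,0
7,9.0,4.39,.,0,64.6,0
7,12.05,3.53,.,0,64.6,0
7,24.22,1.15,.,0,64.6,0
8,0.0,.,319.36,1,70.5,1
8,0.25,3.05,.,0,70.5,1
8,0.52,3.05,.,0,70.5,1
8,0.98,7.31,.,0,70.5,1
8,2.02,7.56,.,0,70.5,1
8,3.53,6.59,.,0,70.5,1
8,5.05,5.88,.,0,70.5,1
8,7.15,4.73,.,0,70.5,1
8,9.07,4.57,.,0,70.5,1
8,12.1,3.0,.,0,70.5,1
8,24.12,1.25,.,0,70.5,1
9,0.0,.,267.84,1,86.4,0
9,0.3,7.37,.,0,86.4,0
9,0.63,9.03,.,0,86.4,0
9,1.05,7.14,.,0,86.4,0
9,2.02,6.33,.,0,86.4,0
9,3.53,5.66,.,0,86.4,0
9,5.02,5.67,.,0,86.4,0
9,7.17,4.24,.,0,86.4,0
9,8.8,4.11,.,0,86.4,0
9,11.6,3.16,.,0,86.4,0
9,24.43,1.12,.,0,86.4,0
10,0.0,.,320.1,1,58.2,1
10,0.37,2.89,.,0,58.2,1
10,0.77,5.22,.,0,58.2,1
10,1.02,6.41,.,0,58.2,1
10,2.05,7.83,.,0,58.2,1
10,3.55,10.21,.,0,58.2,1
10,5.05,9.18,.,0,58.2,1
10,7.08,8.02,.,0,58.2,1
10,9.38,7.14,.,0,58.2,1
10,12.1,5.68,.,0,58.2,1
10,23.7,2.42,.,0,58.2,1
11,0.0,.,319.8,1,65.0,0
11,0.25,4.86,.,0,65.0,0
11,0.5,7.24,.,0,65.0,0
11,0.98,8.0,.,0,65.0,0
11,1.98,6.81,.,0,65.0,0
11,3.6,5.87,.,0,65.0,0
11,5.02,5.22,.,0,65.0,0
11,7.03,4.45,.,0,65.0,0
11,9.03,3.62,.,0,65.0,0
11,12.12,2.69,.,0,65.0,0
11,24.08,0.86,.,0,65.0,0
12,0.0,.,320.65,1,60.5,1
12,0.25,1.25,.,0,60.5,1
12,0.5,3.96,.,0,60.5,1
12,1.0,7.82,.,0,60.5,1
12,2.0,9.72,.,0,60.5,1
12,3.52,9.75,.,0,60.5,1
12,5.07,8.57,.,0,60.5,1
12,7.07,6.59,.,0,60.5,1
12,9.03,6.11,.,0,60.5,1
12,12.05,4.57,.,0,60.5,1
12,24.15,1.17,.,0,60.5,1
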