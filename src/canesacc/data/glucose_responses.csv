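run_id,genotype,timepoint,mean,sd,n
1,NT,6h,13.48,0.16,4
1,Ev.1,6h,13.30,0.66,4
1,Ev.2.2,6h,14.06,0.82,4
1,Ev.2.4,6h,15.11,0.11,4
1,Ev.3.1,6h,14.75,0.26,4
1,Ev.4,6h,11.95,0.32,4
2,NT,6h,21.75,1.08,4
2,Ev.1,6h,21.04,0.76,4
2,Ev.2.2,6h,20.12,0.05,4
2,Ev.2.4,6h,20.27,0.25,4
2,Ev.3.1,6h,19.37,0.70,4
2,Ev.4,6h,18.79,0.86,4
3,NT,6h,7.91,0.15,4
3,Ev.1,6h,7.37,0.28,4
3,Ev.2.2,6h,8.30,0.35,4
3,Ev.2.4,6h,8.24,0.32,4
3,Ev.3.1,6h,8.03,0.50,4
3,Ev.4,6h,7.43,0.22,4
4,NT,6h,10.15,0.37,4
4,Ev.1,6h,9.94,0.28,4
4,Ev.2.2,6h,10.15,0.31,4
4,Ev.2.4,6h,10.53,0.44,4
4,Ev.3.1,6h,10.18,0.43,4
4,Ev.4,6h,9.77,0.18,4
5,NT,6h,21.08,0.46,4
5,Ev.1,6h,21.84,0.87,4
5,Ev.2.2,6h,21.35,0.62,4
5,Ev.2.4,6h,20.05,0.71,4
5,Ev.3.1,6h,21.05,0.92,4
5,Ev.4,6h,19.86,0.41,4
6,NT,6h,6.26,0.13,4
6,Ev.1,6h,6.19,0.18,4
6,Ev.2.2,6h,7.20,0.30,4
6,Ev.2.4,6h,6.95,0.36,4
6,Ev.3.1,6h,6.49,0.10,4
6,Ev.4,6h,6.95,0.06,4
7,NT,6h,7.44,0.30,4
7,Ev.1,6h,7.42,0.15,4
7,Ev.2.2,6h,8.28,0.49,4
7,Ev.2.4,6h,8.00,0.33,4
7,Ev.3.1,6h,7.61,0.19,4
7,Ev.4,6h,7.12,0.29,4
8,NT,6h,16.89,0.57,4
8,Ev.1,6h,16.96,1.04,4
8,Ev.2.2,6h,15.44,0.56,4
8,Ev.2.4,6h,17.93,1.06,4
8,Ev.3.1,6h,17.94,0.58,4
8,Ev.4,6h,16.47,0.34,4
9,NT,6h,16.22,0.67,4
9,Ev.1,6h,15.56,0.35,4
9,Ev.2.2,6h,15.11,0.73,4
9,Ev.2.4,6h,16.18,0.90,4
9,Ev.3.1,6h,15.36,0.87,4
9,Ev.4,6h,16.12,0.79,4
10,NT,6h,13.02,0.37,4
10,Ev.1,6h,13.15,0.23,4
10,Ev.2.2,6h,13.58,0.23,4
10,Ev.2.4,6h,14.62,0.65,4
10,Ev.3.1,6h,12.28,0.09,4
10,Ev.4,6h,12.05,0.58,4
11,NT,6h,10.95,0.51,4
11,Ev.1,6h,12.65,0.12,4
11,Ev.2.2,6h,10.56,0.47,4
11,Ev.2.4,6h,13.56,0.68,4
11,Ev.3.1,6h,12.62,0.29,4
11,Ev.4,6h,10.76,0.58,4
1,NT,48h,23.07,0.46,4
1,Ev.1,48h,20.42,0.77,4
1,Ev.2.2,48h,22.07,0.38,4
1,Ev.2.4,48h,26.85,1.56,4
1,Ev.3.1,48h,26.62,2.80,4
1,Ev.4,48h,19.68,1.24,4
2,NT,48h,31.33,0.86,4
2,Ev.1,48h,35.68,2.58,4
2,Ev.2.2,48h,32.31,0.55,4
2,Ev.2.4,48h,34.74,0.75,4
2,Ev.3.1,48h,31.75,0.04,4
2,Ev.4,48h,28.46,1.45,4
3,NT,48h,8.92,0.66,4
3,Ev.1,48h,9.09,0.66,4
3,Ev.2.2,48h,10.65,0.40,4
3,Ev.2.4,48h,9.53,1.01,4
3,Ev.3.1,48h,10.03,0.75,4
3,Ev.4,48h,9.29,0.28,4
4,NT,48h,13.69,1.38,4
4,Ev.1,48h,13.07,0.39,4
4,Ev.2.2,48h,14.72,1.19,4
4,Ev.2.4,48h,13.95,0.56,4
4,Ev.3.1,48h,14.66,1.00,4
4,Ev.4,48h,13.37,0.88,4
5,NT,48h,31.77,0.65,4
5,Ev.1,48h,38.00,0.96,4
5,Ev.2.2,48h,33.93,1.53,4
5,Ev.2.4,48h,33.49,1.59,4
5,Ev.3.1,48h,29.62,0.76,4
5,Ev.4,48h,31.74,0.88,4
6,NT,48h,8.49,0.28,4
6,Ev.1,48h,8.51,0.17,4
6,Ev.2.2,48h,8.93,0.24,4
6,Ev.2.4,48h,9.31,0.44,4
6,Ev.3.1,48h,8.63,0.49,4
6,Ev.4,48h,8.44,1.13,4
7,NT,48h,8.74,0.29,4
7,Ev.1,48h,8.74,0.06,4
7,Ev.2.2,48h,10.28,0.85,4
7,Ev.2.4,48h,9.94,0.31,4
7,Ev.3.1,48h,9.17,0.10,4
7,Ev.4,48h,8.76,0.71,4
8,NT,48h,26.27,0.23,4
8,Ev.1,48h,29.33,3.55,4
8,Ev.2.2,48h,22.39,0.44,4
8,Ev.2.4,48h,29.01,2.81,4
8,Ev.3.1,48h,28.71,3.22,4
8,Ev.4,48h,24.97,1.00,4
9,NT,48h,25.75,2.74,4
9,Ev.1,48h,22.29,2.23,4
9,Ev.2.2,48h,22.01,2.71,4
9,Ev.2.4,48h,22.67,1.63,4
9,Ev.3.1,48h,22.45,3.09,4
9,Ev.4,48h,22.65,4.00,4
10,NT,48h,25.17,0.28,4
10,Ev.1,48h,23.02,1.78,4
10,Ev.2.2,48h,24.23,0.76,4
10,Ev.2.4,48h,24.89,2.11,4
10,Ev.3.1,48h,22.66,1.30,4
10,Ev.4,48h,20.14,0.44,4
11,NT,48h,16.89,1.53,4
11,Ev.1,48h,25.51,0.63,4
11,Ev.2.2,48h,16.02,0.87,4
11,Ev.2.4,48h,22.97,0.88,4
11,Ev.3.1,48h,23.26,1.39,4
11,Ev.4,48h,15.57,1.13,4
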