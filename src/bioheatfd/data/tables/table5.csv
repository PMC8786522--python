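i,j,k,T_2min,T_4min,T_6min,note
0,0,0,14.44,12.53,11.94,
0,1,0,14.83,13.52,13.31,
0,-1,0,14.83,13.52,13.31,
0,0,1,15.13,14.66,14.29,
0,0,-1,15.13,14.66,14.29,
0,1,1,15.54,15.03,14.57,
0,1,-1,15.54,15.03,14.57,
1,0,0,16.04,15.72,15.37,
1,1,0,16.84,16.53,16.15,
1,-1,0,16.84,16.53,16.15,
1,0,1,17.53,17.05,15.64,
1,0,-1,17.53,17.05,15.64,
1,1,1,18.16,17.77,15.36,
1,-1,1,18.16,17.77,15.36,
1,1,-1,18.43,18.15,17.54,
1,-1,-1,18.43,18.15,17.54,
1,2,0,18.93,18.53,18.26,
1,-2,0,18.93,18.53,18.26,
1,0,2,19.55,18.94,18.55,
1,0,-2,19.55,18.94,18.55,
1,2,1,20.17,19.81,19.53,
1,-2,1,20.17,19.81,19.53,
1,2,-1,20.62,20.22,19.91,
1,-2,-1,20.62,20.22,19.91,
1,2,2,21.33,20.92,20.55,
1,-2,2,21.33,20.92,20.55,
1,2,-2,22.07,21.77,21.35,
1,-2,-2,22.07,21.77,21.35,
2,0,0,22.96,22.55,21.97,
2,1,0,23.34,22.93,22.57,
2,-1,0,23.34,22.93,22.57,
2,0,1,24.04,23.64,23.13,
2,0,-1,24.04,23.64,23.13,
2,1,1,24.82,24.33,23.88,
2,-1,1,24.82,24.33,23.88,
2,1,-1,25.15,24.94,24.59,
2,-1,-1,25.15,24.94,24.59,
2,2,0,25.23,24.96,24.33,
2,-2,0,25.23,24.96,24.33,
2,0,2,25.91,25.63,24.92,
2,0,-2,25.91,25.63,24.92,
2,2,1,26.35,26.04,25.55,
2,-2,1,26.35,26.04,25.55,
2,2,-1,26.91,26.62,26.16,
2,-2,-1,26.91,26.62,26.16,
2,2,2,27.33,27.05,26.68,
2,-2,2,27.33,27.05,26.68,
2,2,-2,27.92,27.55,26.98,
2,-2,-2,27.92,27.55,26.98,
3,0,0,29.33,29.07,28.34,
3,1,0,30.16,29.66,29.14,
3,-1,0,30.16,29.66,29.14,
3,0,1,30.63,30.23,29.65,
3,0,-1,30.63,30.23,29.65,
3,1,1,31.07,30.67,30.15,
3,-1,1,31.07,30.67,30.15,
3,1,-1,31.73,31.13,30.44,
3,-1,-1,31.73,31.13,30.44,
3,2,0,32.18,31.59,30.68,
3,-2,0,32.18,31.59,30.68,
3,0,2,32.84,32.33,31.77,
3,0,-2,32.84,32.33,31.77,
3,2,1,33.35,32.95,32.39,
3,-2,1,33.35,32.95,32.39,
3,2,-1,34.04,33.44,32.88,
3,-2,-1,34.04,33.44,32.88,
3,2,2,35.13,34.81,34.72,
3,-2,2,35.13,34.81,34.72,
3,2,-2,36.34,36.17,36.05,
3,-2,-2,36.34,36.17,36.05,
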