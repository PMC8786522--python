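i,j,k,T_2min,T_4min,T_6min,note
0,0,0,14.21,12.43,11.65,
0,1,0,14.63,13.31,12.90,
0,-1,0,14.63,13.31,12.90,
0,0,1,14.94,14.43,14.05,
0,0,-1,14.94,14.43,14.05,
0,1,1,15.36,14.82,14.28,
0,1,-1,15.36,14.82,14.28,
1,0,0,15.83,15.43,15.20,
1,1,0,16.66,16.35,15.92,
1,-1,0,16.66,16.35,15.92,
1,0,1,17.23,16.84,15.31,
1,0,-1,17.23,16.84,15.31,
1,1,1,17.84,17.54,15.15,
1,-1,1,17.84,17.54,15.15,
1,1,-1,18.27,17.93,17.24,
1,-1,-1,18.27,17.93,17.24,
1,2,0,18.75,18.34,17.93,
1,-2,0,18.75,18.34,17.93,
1,0,2,19.32,18.73,18.22,
1,0,-2,19.32,18.73,18.23,
1,2,1,19.92,19.65,19.31,
1,-2,1,19.92,19.65,19.31,
1,2,-1,20.47,20.03,19.74,
1,-2,-1,20.47,20.03,19.74,
1,2,2,21.05,20.64,20.23,
1,-2,2,21.05,20.64,20.23,
1,2,-2,21.82,21.52,21.12,
1,-2,-2,21.82,21.52,21.12,
2,0,0,22.73,22.37,21.84,
2,1,0,23.13,22.77,22.25,
2,-1,0,23.13,22.77,22.25,
2,0,1,23.81,23.44,22.83,
2,0,-1,23.81,23.44,22.83,
2,1,1,24.58,24.13,23.65,
2,-1,1,24.58,24.13,23.65,
2,1,-1,24.95,24.64,24.27,
2,-1,-1,24.95,24.64,24.27,
2,2,0,25.05,24.73,24.18,
2,-2,0,25.05,24.73,24.18,
2,0,2,25.64,25.34,24.72,
2,0,-2,25.64,25.34,24.72,
2,2,1,26.19,25.87,25.36,
2,-2,1,26.19,25.87,25.36,
2,2,-1,26.72,26.41,25.93,
2,-2,-1,26.72,26.41,25.93,
2,2,2,27.14,26.83,26.33,
2,-2,2,27.14,26.83,26.33,
2,2,-2,27.66,27.28,26.67,
2,-2,-2,27.66,27.28,26.67,
3,0,0,29.25,28.85,28.10,
3,1,0,29.83,29.34,28.95,
3,-1,0,29.83,29.34,28.95,
3,0,1,30.45,30.04,29.43,
3,0,-1,30.45,30.04,29.43,
3,1,1,30.82,30.44,29.96,
3,-1,1,30.82,30.44,29.96,
3,1,-1,31.53,30.93,30.15,
3,-1,-1,31.53,30.93,30.15,
3,2,0,31.91,31.22,30.35,
3,-2,0,31.91,31.22,30.35,
3,0,2,32.66,32.14,31.45,
3,0,-2,32.66,32.14,31.45,
3,2,1,33.14,32.74,32.16,
3,-2,1,33.14,32.74,32.16,
3,2,-1,33.83,33.26,32.68,
3,-2,-1,33.73,33.26,32.68,y-mirror of (3 2 -1) differs by 0.10 at 2 min
3,2,2,34.92,34.62,34.44,
3,-2,2,34.92,34.62,34.44,
3,2,-2,36.16,35.96,35.83,
3,-2,-2,36.16,35.96,35.83,
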