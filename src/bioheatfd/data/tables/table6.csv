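i,j,k,T_2min,T_4min,T_6min,note
0,0,0,14.62,12.83,12.15,
0,1,0,14.92,13.77,13.33,
0,-1,0,14.92,13.77,13.33,
0,0,1,15.33,14.98,14.55,
0,0,-1,15.33,14.98,14.55,
0,1,1,15.77,15.26,14.77,
0,1,-1,15.77,15.26,14.77,
1,0,0,16.24,15.96,15.66,
1,1,0,17.05,16.77,16.33,
1,-1,0,17.05,16.77,16.33,
1,0,1,17.76,17.33,15.94,
1,0,-1,17.76,17.33,15.94,
1,1,1,18.34,17.95,15.66,
1,-1,1,18.34,17.95,15.66,
1,1,-1,18.77,18.45,17.86,
1,-1,-1,18.77,18.45,17.86,
1,2,0,19.15,18.74,18.59,
1,-2,0,19.15,18.74,18.59,
1,0,2,19.73,19.23,18.86,
1,0,-2,19.73,19.23,18.86,
1,2,1,20.34,20.15,19.87,
1,-2,1,20.34,20.15,19.87,
1,2,-1,20.92,20.42,20.14,
1,-2,-1,20.92,20.42,20.14,
1,2,2,21.63,21.13,20.86,
1,-2,2,21.63,21.13,20.86,
1,2,-2,22.27,21.96,21.66,
1,-2,-2,22.27,21.96,21.66,
2,0,0,23.14,22.77,21.96,
2,1,0,23.55,23.11,22.76,
2,-1,0,23.55,23.11,22.76,
2,0,1,24.25,23.85,23.34,
2,0,-1,24.25,23.85,23.34,
2,1,1,25.16,24.56,24.18,
2,-1,1,25.16,24.56,24.18,
2,1,-1,25.44,25.17,24.83,
2,-1,-1,25.44,25.17,24.83,
2,2,0,25.71,25.35,24.96,
2,-2,0,25.71,25.35,24.96,
2,0,2,26.13,25.91,25.15,
2,0,-2,26.13,25.91,25.15,
2,2,1,26.67,26.26,25.77,
2,-2,1,26.67,26.26,25.77,
2,2,-1,27.28,26.98,26.44,
2,-2,-1,27.28,26.98,26.44,
2,2,2,27.66,27.25,26.94,
2,-2,2,27.66,27.25,26.94,
2,2,-2,28.14,27.83,27.27,
2,-2,-2,28.14,27.83,27.27,
3,0,0,29.66,29.27,28.67,
3,1,0,30.45,29.97,29.37,
3,-1,0,30.45,29.97,29.37,
3,0,1,30.93,30.53,29.96,
3,0,-1,30.93,30.53,29.96,
3,1,1,31.26,30.85,30.45,
3,-1,1,31.26,30.85,30.45,
3,1,-1,31.97,31.53,30.84,
3,-1,-1,31.97,31.53,30.84,
3,2,0,32.45,31.86,30.94,
3,-2,0,32.45,31.86,30.94,
3,0,2,33.14,32.66,32.05,
3,0,-2,33.14,32.66,32.05,
3,2,1,33.66,33.15,32.66,
3,-2,1,33.66,33.15,32.66,
3,2,-1,34.27,33.86,33.15,
3,-2,-1,34.27,33.86,33.15,
3,2,2,35.49,35.08,34.98,
3,-2,2,35.49,35.08,34.98,
3,2,-2,36.72,36.52,36.43,
3,-2,-2,36.72,36.52,36.43,
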