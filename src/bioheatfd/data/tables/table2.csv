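i,j,k,T,note
0,0,0,9.13,
0,1,0,9.94,
0,-1,0,9.94,
0,0,1,9.98,
0,0,-1,9.98,
0,1,1,11.23,
0,-1,1,11.23,
0,1,-1,11.28,
0,-1,-1,11.28,
1,0,0,11.09,
1,1,0,12.71,
1,-1,0,12.71,
1,0,1,12.68,
1,0,-1,12.68,
1,1,1,13.74,
1,-1,1,13.74,
1,1,-1,13.77,
1,-1,-1,13.77,
1,2,0,15.58,
1,-2,0,15.58,
1,0,2,15.61,
1,0,-2,15.61,
1,2,1,16.54,
1,-2,1,16.54,
1,2,-1,16.51,
1,-2,-1,16.51,
1,2,2,18.44,
1,-2,2,18.44,
1,2,-2,18.73,
1,-2,-2,18.73,
2,0,0,18.92,
2,1,0,20.85,
2,-1,0,20.85,
2,0,1,20.83,
2,0,-1,20.83,
2,1,1,23.07,
2,-1,1,23.07,
2,1,-1,23.10,
2,-1,-1,23.10,
2,2,0,24.26,
2,-2,0,24.26,
2,0,2,24.63,
2,0,-2,24.63,
2,2,1,28.15,
2,-2,1,28.15,
2,2,-1,28.18,
2,-2,-1,28.18,
2,2,2,29.08,
2,-2,2,29.08,
2,2,-2,29.01,
2,-2,-2,29.01,
3,0,0,29.20,
3,1,0,31.94,
3,-1,0,31.94,
3,0,1,31.97,
3,0,-1,31.97,
3,1,1,32.75,
3,-1,1,32.75,
3,1,-1,33.87,
3,-1,-1,33.87,
3,2,0,35.23,
3,-2,0,35.23,
3,0,2,35.25,
3,0,-2,35.25,
3,2,1,36.11,
3,-2,1,36.11,
3,2,-1,36.13,
3,-2,-1,36.13,
3,2,2,37.82,
3,-2,2,37.82,
3,2,-2,37.85,
3,-2,-2,37.85,
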