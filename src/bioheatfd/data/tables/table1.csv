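i,j,k,T,note
0,0,0,8.53,
0,1,0,9.72,
0,-1,0,9.72,
0,0,1,9.87,
0,0,-1,9.87,
0,1,1,11.17,
0,-1,1,11.17,
0,1,-1,11.21,
0,-1,-1,11.21,
1,0,0,10.89,
1,1,0,12.51,
1,-1,0,12.51,
1,0,1,12.58,
1,0,-1,12.58,
1,1,1,13.48,
1,-1,1,13.48,
1,1,-1,13.53,
1,-1,-1,13.53,
1,2,0,15.03,
1,-2,0,15.03,
1,0,2,15.06,
1,0,-2,15.06,
1,2,1,16.32,
1,-2,1,16.32,
1,2,-1,16.29,
1,-2,-1,16.29,
1,2,2,18.25,
1,-2,2,18.25,
1,2,-2,18.27,
1,-2,-2,18.27,
2,0,0,18.02,
2,1,0,20.35,
2,-1,0,20.35,
2,0,1,20.38,
2,0,-1,20.38,
2,1,1,22.79,
2,-1,1,22.79,
2,1,-1,22.76,
2,-1,-1,22.76,
2,2,0,24.00,
2,-2,0,24.00,
2,0,2,24.03,
2,0,-2,24.03,
2,2,1,27.65,
2,-2,1,27.65,
2,2,-1,27.68,
2,-2,-1,27.68,
2,2,2,28.78,
2,-2,2,28.78,
2,2,-2,28.81,
2,-2,-2,28.81,
3,0,0,29.11,
3,1,0,31.34,
3,-1,0,31.34,
3,0,1,31.37,
3,0,-1,31.37,
3,1,1,32.68,
3,-1,1,32.68,
3,1,-1,32.71,
3,-1,-1,32.71,
3,2,0,34.03,
3,-2,0,34.03,
3,0,2,34.05,
3,0,-2,34.05,
3,2,1,35.21,
3,-2,1,35.21,
3,2,-1,35.24,
3,-2,-1,35.24,
3,2,2,37.03,
3,-2,2,37.03,
3,2,-2,37.35,
3,-2,-2,37.35,
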