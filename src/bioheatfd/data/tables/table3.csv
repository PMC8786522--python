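i,j,k,T,note
0,0,0,9.72,
0,1,0,10.12,
0,-1,0,10.12,
0,0,1,10.17,
0,0,-1,10.17,
0,1,1,11.41,
0,-1,1,11.41,
0,1,-1,11.62,
0,-1,-1,11.62,
1,0,0,12.01,
1,1,0,13.16,
1,-1,0,13.16,
1,0,1,13.19,
1,0,-1,13.19,
1,1,1,13.93,
1,-1,1,13.93,
1,1,-1,13.96,
1,-1,-1,13.96,
1,2,0,15.88,
1,-2,0,15.88,
1,0,2,15.91,
1,0,-2,15.91,
1,2,1,16.67,
1,-2,1,16.67,
1,2,-1,16.71,
1,-2,-1,16.71,
1,2,2,18.76,
1,-2,2,18.76,
1,2,-2,18.80,
1,-2,-2,18.80,
2,0,0,19.09,
2,1,0,20.98,
2,-1,0,20.98,
2,0,1,21.04,
2,0,-1,21.04,
2,1,1,23.24,
2,-1,1,23.24,
2,1,-1,23.22,
2,-1,-1,23.22,
2,2,0,24.34,
2,-2,0,24.34,
2,0,2,24.76,
2,0,-2,24.76,
2,2,1,28.24,
2,-2,1,28.24,
2,2,-1,28.41,
2,-2,-1,28.41,
2,2,2,29.53,
2,-2,2,29.53,
2,2,-2,29.71,
2,-2,-2,29.71,
3,0,0,29.82,
3,1,0,32.14,
3,-1,0,32.14,
3,0,1,32.19,
3,0,-1,31.19,breaks z-mirror with (3 0 1)=32.19; presumed transcription slip
3,1,1,33.06,
3,-1,1,33.06,
3,1,-1,34.02,
3,-1,-1,34.02,
3,2,0,35.63,
3,-2,0,35.63,
3,0,2,35.59,
3,0,-2,35.59,
3,2,1,36.23,
3,-2,1,36.23,
3,2,-1,36.21,
3,-2,-1,36.21,
3,2,2,37.95,
3,-2,2,37.95,
3,2,-2,37.97,
3,-2,-2,37.97,
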