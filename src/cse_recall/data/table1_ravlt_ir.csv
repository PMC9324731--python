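item,primacy,middle,recency,frequency,delta,U_delta,z_r,U_zr
1,0.00,6.31,-8.33,4.80,-0.81,0.28,-0.80,5.28
2,-0.26,6.31,-7.38,4.85,-0.54,0.28,-0.24,4.86
3,-0.66,6.31,-6.46,4.88,0.57,0.30,0.19,4.48
4,-1.17,6.31,-5.58,3.99,1.38,0.36,0.34,4.16
5,-1.77,6.31,-4.73,3.25,-0.64,0.28,0.42,3.92
6,-2.43,6.31,-3.92,3.56,0.32,0.30,0.63,3.76
7,-3.15,6.31,-3.15,4.31,1.16,0.34,0.84,3.71
8,-3.92,6.31,-2.43,3.39,-0.09,0.28,0.66,3.79
9,-4.73,6.31,-1.77,4.41,1.31,0.36,0.78,3.96
10,-5.58,6.31,-1.17,4.06,0.64,0.32,0.55,4.22
11,-6.46,6.31,-0.66,4.27,0.74,0.32,0.33,4.56
12,-7.38,6.31,-0.26,5.44,-0.72,0.28,0.20,4.97
13,-8.33,6.31,0.00,3.57,0.23,0.30,-0.66,5.40
14,-9.30,6.31,0.00,3.24,-1.46,0.30,-1.38,5.87
15,-10.30,6.31,0.00,4.93,-2.09,0.34,-1.86,6.36
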