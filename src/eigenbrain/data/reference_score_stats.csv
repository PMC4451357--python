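slice,rank,nc_mean,nc_sd,ad_mean,ad_sd,printed_p
60,1,-3.36,20.01,11.75,27.91,0.01
70,1,-6.84,25.60,23.92,28.33,0.00
80,1,-7.48,29.05,26.18,27.04,0.00
90,1,6.79,32.04,-23.75,24.86,0.00
100,1,-6.93,34.25,24.27,30.89,0.00
110,1,-6.95,31.89,24.31,24.10,0.00
120,1,-5.93,31.60,20.74,23.14,0.00
130,1,5.02,28.13,-17.56,28.09,0.00
140,1,4.27,25.02,-14.94,22.06,0.00
150,1,5.51,18.50,-19.30,30.21,0.00
60,2,2.82,18.77,-9.87,27.93,0.03
70,2,0.43,21.20,-1.50,36.97,0.79
80,2,-0.65,22.00,2.26,33.36,0.67
90,2,0.42,21.94,-1.46,32.98,0.78
100,2,2.51,23.05,-8.79,31.63,0.09
110,2,0.48,25.03,-1.67,32.93,0.75
120,2,-0.33,24.02,1.14,31.84,0.82
130,2,-1.40,21.70,4.90,27.75,0.27
140,2,-1.34,18.13,4.70,27.10,0.27
150,2,-2.22,18.08,7.78,24.66,0.05
60,3,0.11,18.95,-0.39,21.44,0.91
70,3,1.84,19.88,-6.44,22.86,0.09
80,3,-0.25,21.84,0.87,25.08,0.83
90,3,-1.88,20.16,6.57,21.48,0.07
100,3,0.63,20.16,-2.22,23.74,0.57
110,3,1.95,18.17,-6.81,29.05,0.14
120,3,-1.07,16.73,3.74,25.61,0.35
130,3,-0.59,17.75,2.06,19.20,0.52
140,3,3.12,17.91,-10.93,14.69,0.00
150,3,1.42,16.56,-4.97,13.98,0.05
60,4,-1.27,15.47,4.43,25.32,0.27
70,4,1.99,17.76,-6.95,22.50,0.06
80,4,1.46,21.14,-5.12,18.85,0.12
90,4,0.31,19.66,-1.09,23.73,0.78
100,4,-1.56,18.77,5.47,21.18,0.12
110,4,-0.31,19.32,1.07,17.30,0.72
120,4,-0.32,16.83,1.13,21.16,0.74
130,4,1.61,17.00,-5.62,18.51,0.07
140,4,2.11,16.81,-7.39,16.29,0.01
150,4,1.17,13.52,-4.11,18.51,0.17
60,5,1.51,14.13,-5.29,23.59,0.16
70,5,-0.03,16.69,0.09,23.25,0.98
80,5,-0.72,17.80,2.52,24.31,0.51
90,5,-0.54,18.05,1.89,24.49,0.63
100,5,0.84,16.32,-2.95,25.35,0.46
110,5,0.54,16.78,-1.87,22.19,0.60
120,5,-2.21,18.00,7.74,10.70,0.00
130,5,1.39,14.21,-4.86,23.47,0.19
140,5,0.44,15.37,-1.56,17.70,0.59
150,5,0.27,14.35,-0.94,13.89,0.69
60,6,-1.29,13.10,4.50,23.71,0.22
70,6,-0.96,16.08,3.35,20.79,0.32
80,6,-1.34,17.47,4.68,21.78,0.19
90,6,-1.80,16.79,6.29,23.33,0.10
100,6,-0.53,15.58,1.85,24.87,0.63
110,6,-1.09,16.07,3.83,20.43,0.25
120,6,-1.31,14.81,4.57,21.45,0.18
130,6,2.01,15.42,-7.04,17.25,0.02
140,6,1.21,14.37,-4.24,17.85,0.15
150,6,0.17,13.52,-0.58,15.14,0.82
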