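object,Age,DFS,Gender,LOC,AdjRadio,AdjChem,G27,G55,G64,G108,G171,G278,G373,G404,G669,G701,G1269,G1271,G1273,G1333,G1339,G1509,G1612,d,event
b1,75,40,2,1,2,1,4,4.55,3.65,3.31,6.47,4.5,7.05,6.6,4.24,3.99,5.79,6.26,5.79,5.9,4.63,4.64,3.99,0,0
b2,61,65,2,1,2,1,4.33,3.83,4.85,3.2,6.95,4,9.24,6.49,5.1,5.13,6.23,4.65,4.46,5.3,4.05,6.86,4.91,1,0
b3,62,37,1,1,2,1,3.5,2.76,3.83,4.11,6.34,5,7.98,5.48,3.02,4.8,3.9,3.93,2.91,7.17,5.65,4.03,5.3,3,0
b4,47,27,1,1,2,2,4.95,4,4.02,3.48,5.59,4.6,10.35,5.81,3.49,5.21,5.52,5.53,5.04,7.2,5.04,5.1,5.14,3,1
b5,70,106,2,1,1,2,3.43,3.91,4.35,2.95,5.55,4.8,8.54,6.39,3.69,3.51,4.72,5.22,8.03,6.12,4.03,5.03,5.83,2,1
b6,28,85,2,2,2,2,3.95,5.73,6.82,3.71,6.16,5.2,9,7.7,2.98,3.72,4.23,4.3,5.96,7.01,6,3.76,5.88,0,0
b7,54,21,2,1,2,2,3.36,4.6,4.3,2.81,6.6,5.5,7.89,8.31,5.09,4.77,4.2,6.39,4.75,5.98,4.97,4.47,4.96,2,1
b8,46,64,2,2,1,1,3.85,7.26,3.72,3.8,6.13,5.3,7.65,7.49,3.61,4.12,4.5,4.53,6.93,5.3,6.2,3.65,4.16,1,0
b9,61,14,2,2,2,2,3.9,4.72,3.65,5.6,7.59,4.6,9.05,7.58,3.2,4.75,4.32,4.91,5.3,5.58,4.6,5.75,6.05,1,0
b10,55,19,2,3,1,1,4.29,3.38,3.72,4.6,5.9,4.2,8.24,5.33,3.51,4,3.83,6.26,4.93,4.21,5.53,3.67,5.26,2,1
b11,57,36,1,1,2,1,4.01,3.43,5.36,2.95,6.29,4.7,6.73,7.21,3.81,4.53,4.97,5.01,4.62,4.03,4.39,4.15,6.92,2,1
b12,62,56,2,2,2,1,3.3,3.68,3.4,3.96,8.21,5.2,8.44,7.19,5.01,4.4,5.69,4.75,5.36,5.7,4.46,5.07,6.82,2,1
b13,61,63,2,2,1,2,4.01,5.08,3.95,3.38,7.19,4.9,8.05,7.09,4.23,4.16,4.83,4.86,5.92,6.25,4.67,4.78,6.23,0,0
b14,49,17,2,3,1,1,3.65,7.26,4.1,3.21,5.51,4.7,6.1,5.97,2.45,3.94,4.16,4.26,6.93,5.7,6.02,4.1,4.91,3,1
b15,60,38,2,4,1,2,3.8,3.53,3.99,3.3,5.53,4.4,6.73,5.57,4.24,4.88,3.7,6.61,6.88,6.3,5.5,4.24,6.75,3,1
b16,60,16,1,1,1,2,4.2,3.75,3.47,4.6,6.06,4.9,8.35,6.12,3.36,4.3,5.31,5.95,5.13,6.01,5.33,3.96,8.52,1,0
b17,60,38,2,2,1,2,5,4.9,4.19,3.05,7.55,4.3,9.28,6.28,2.86,5.05,5.48,4.46,4.81,5.07,7.8,6.86,6.39,0,1
b18,73,57,2,2,2,1,3.93,3.25,4.02,4.09,6.23,4.2,6.15,5.29,3.95,4.44,4.27,5.57,5.42,5.81,4,4.49,5.01,0,0
b19,48,108,1,3,2,1,4.21,4.15,5.44,3.41,5.57,5,8.65,6.86,3.2,4.21,4.83,5.74,5.22,5.29,5.87,4.28,5.95,1,1
b20,71,55,2,1,2,2,3.92,5.73,3.4,5.51,6.37,5.3,6.92,6.9,3.15,5.75,4.72,4.6,4.94,7.61,7.81,5.71,5.91,2,0
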