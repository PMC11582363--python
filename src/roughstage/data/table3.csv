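object,a1,a2,a3,a4,a5,event
P1,45,1,3.09,6.29,4.50,1
P2,35,2,4.04,8.54,3.83,1
P3,65,1,5.01,6.34,2.76,0
P4,36,1,4.02,8.46,4.45,0
P5,64,2,3.04,9.24,3.91,0
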