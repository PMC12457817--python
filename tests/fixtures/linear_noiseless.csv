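y,x,w1,w2
1.9000000000000001,1,1,1
1.4,1,0,1
1.7,1,0,0
0.7,0,0,1
1.5,0,1,0
1.4,1,0,1
2.2,1,1,0
1.0,0,0,0
1.0,0,0,0
1.0,0,0,0
1.0,0,0,0
0.7,0,0,1
2.2,1,1,0
1.4,1,0,1
2.2,1,1,0
1.4,1,0,1
0.7,0,0,1
1.7,1,0,0
1.9000000000000001,1,1,1
1.9000000000000001,1,1,1
1.0,0,0,0
1.9000000000000001,1,1,1
1.2,0,1,1
1.7,1,0,0
1.5,0,1,0
2.2,1,1,0
1.5,0,1,0
1.5,0,1,0
1.2,0,1,1
1.7,1,0,0
2.2,1,1,0
1.2,0,1,1
1.2,0,1,1
1.5,0,1,0
1.9000000000000001,1,1,1
1.7,1,0,0
0.7,0,0,1
1.4,1,0,1
1.2,0,1,1
0.7,0,0,1
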