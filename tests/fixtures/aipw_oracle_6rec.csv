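y,x,e1,e0,g
0.4547,0,1.1964,-0.3044,0.555
0.9554,0,-0.5611,0.2312,0.7313
-0.9376,1,-0.6559,-0.8571,0.6417
-0.3043,1,0.7145,-2.2746,0.3827
0.8887,0,-0.034,-0.5151,0.7042
0.9253,0,0.5603,0.6045,0.5842
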