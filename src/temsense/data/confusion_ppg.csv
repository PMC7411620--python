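7,0,4,0
0,17,1,4
2,2,35,2
0,3,0,7
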