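7,1,2,1
0,18,5,0
2,3,29,5
0,0,4,7
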