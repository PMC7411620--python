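7,0,1,0
1,16,3,2
1,6,35,2
0,0,1,9
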