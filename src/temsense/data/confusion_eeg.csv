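6,1,2,0
0,15,6,1
4,2,33,1
1,2,1,9
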