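niris,marshall_I,marshall_II,marshall_III,marshall_IV,marshall_V_VI
0,319,1,0,0,0
1,14,208,3,0,0
2,6,739,232,2,318
3,0,72,54,28,372
4,0,7,4,18,634
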