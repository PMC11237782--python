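profile,r1,r2,r3,r4,r5,r6,r7
BB,5,4,5,5,3,4,5
FG,5,1,4,2,3,4,4
LA,5,4,5,5,4,4,4
TM,5,4,5,5,3,4,5
XY2,5,4,5,5,4,4,5
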