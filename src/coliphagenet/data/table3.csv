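phage,B,C,K-12,1358,1180,1195,5924,1220,1162,1225,1337,7431,103
i527,0,1,0,0,0,0,1,1,0,1,0,0,0
i6653,1,1,1,0,0,0,1,0,0,1,0,0,0
i6721,0,1,0,1,0,0,0,1,1,1,0,0,1
i9006,0,1,0,0,0,0,0,0,0,0,0,0,0
i9105,0,1,0,0,0,0,0,0,0,1,0,0,0
i9208,0,1,1,0,0,0,1,0,0,1,0,0,0
i9344,0,1,1,0,0,0,1,0,0,1,0,0,0
i9346,0,1,0,0,0,0,0,0,0,1,0,0,0
i9930-1,0,1,1,0,0,0,1,0,0,1,0,0,0
i9930-2,0,1,1,0,0,0,1,0,0,0,0,0,0
Lust,1,1,1,0,0,0,1,1,1,0,0,0,0
Greed,1,1,1,0,0,0,1,1,1,0,0,1,0
K30,1,1,0,0,0,0,0,1,1,1,0,0,0
P22,1,0,0,0,0,1,0,1,0,0,0,1,0
T2,1,1,1,1,1,0,1,1,1,1,0,1,1
T3,1,1,1,0,0,1,1,1,1,0,0,1,1
T6,1,1,1,0,1,1,1,1,1,0,0,1,1
T7,1,1,1,0,0,1,1,1,0,0,0,1,0
N4,0,1,1,1,1,1,0,1,1,1,1,0,1
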