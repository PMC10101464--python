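strain,phylotype,group
B,,laboratory
C,,laboratory
K-12,,laboratory
1358,A,UTI
1180,A,UTI
1195,B1,UTI
5924,B1,UTI
1220,B2,UTI
1162,B2,UTI
1225,B2,UTI
1337,B2,UTI
7431,D,UTI
103,F,OAB
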