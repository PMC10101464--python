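category,count
both,48
n4_only,23
t2_only,15
neither,17
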