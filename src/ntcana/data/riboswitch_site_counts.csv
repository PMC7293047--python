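NtC,Inside,Outside
AA00,766,3909
AA01,29,290
AA05,21,32
AA12,23,30
AB04,19,14
IC01,14,11
OP05,22,5
OP15,33,10
NANT,460,1374
Rest,390,1593
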