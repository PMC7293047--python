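NtC,Xray,CryoEM
AA00,8415,9768
AA03,299,96
AA04,996,732
AA08,3109,4586
AA06,176,331
AB05,425,403
OP03,66,154
OP04,147,96
NANT,6933,8926
Rest,3426,3829
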