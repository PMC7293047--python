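ntc,cana
AA00,AAA
AA02,AAA
AA03,AAA
AA04,AAA
AA06,AAA
AA08,AAA
AA01,AAw
AA05,AAw
AA07,AAw
AA09,AAw
AA12,AAw
AA10,AAu
AA11,AAu
AA13,AAu
AB01,A-B
AB02,A-B
AB03,A-B
AB04,A-B
AB05,A-B
BA01,B-A
BA02,B-A
BA03,B-A
BA04,B-A
BA05,B-A
BA08,B-A
BA09,B-A
BA10,B-A
BB00,BBB
BB01,BBB
BB02,BBw
BB03,BBw
BB04,BBw
BB05,BBw
BB17,BBw
BB07,B12
BB10,B12
BB08,BB2
BB11,BB2
BB12,miB
BB13,miB
BB14,miB
BB15,miB
BB16,miB
BB20,miB
IC01,ICL
IC02,ICL
IC03,ICL
IC04,ICL
IC05,ICL
IC06,ICL
IC07,ICL
OP01,OPN
OP02,OPN
OP03,OPN
OP04,OPN
OP05,OPN
OP06,OPN
OP07,OPN
OP08,OPN
OP09,OPN
OP10,OPN
OP11,OPN
OP12,OPN
OP13,OPN
OP14,OPN
OP15,OPN
OP16,OPN
OP17,OPN
OP18,OPN
OP19,OPN
OP20,OPN
OP21,OPN
OP22,OPN
OP23,OPN
OP24,OPN
OP25,OPN
OP26,OPN
OP27,OPN
OP28,OPN
OP29,OPN
OP30,OPN
OP31,OPN
OP32,OPN
OP33,OPN
AAS1,SYN
BBS1,SYN
ABS1,SYN
BAS1,SYN
ZZ1S,SYN
ICS1,SYN
ZZ01,ZZZ
ZZ02,ZZZ
ZZ03,ZZZ
ZZ04,ZZZ
ZZS1,ZZZ
ZZS2,ZZZ
NANT,NAN
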