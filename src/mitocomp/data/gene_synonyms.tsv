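alias	canonical
yejr	ccmf
yeju	ccmc
yejv	ccmb
yejw	ccma
atpa	atp1
cytb	cob
cob1	cob
nd1	nad1
nd2	nad2
nd3	nad3
nd4	nad4
nd4l	nad4l
nd5	nad5
nd6	nad6
coxi	cox1
coxii	cox2
coxiii	cox3
co1	cox1
co2	cox2
co3	cox3
rrnl	rnl
rrns	rns
rnl-l	rnl
tufa1	tufa
rps3a	rps3
rps3b	rps3
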