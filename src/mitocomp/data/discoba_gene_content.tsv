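taxon	atp1	atp3	atp6	atp8	atp9	ccma	ccmb	ccmc	ccmf	cob	cox1	cox11	cox15	cox2	cox3	nad1	nad10	nad11	nad2	nad3	nad4	nad4l	nad5	nad6	nad7	nad8	nad9	rpl1	rpl10	rpl11	rpl14	rpl16	rpl18	rpl19	rpl2	rpl20	rpl27	rpl31	rpl32	rpl34	rpl35	rpl36	rpl5	rpl6	rpoa	rpob	rpoc	rpod	rps1	rps10	rps11	rps12	rps13	rps16	rps19	rps2	rps3	rps4	rps7	rps8	sdh2	sdh3	sdh4	secy	tata	tatc	tufa
Acrasis_kona	1	1	1	1	1	0	0	0	0	1	1	0	0	1	1	1	1	0	1	1	1	1	1	1	0	1	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0	1	0	0	0	0	1	0	0	1	0	1	1	0	0	0	0
Naegleria_gruberi	1	1	1	1	1	0	0	1	1	1	1	1	0	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	0	0	1	1	1	0	1	0	0	0	0	0	0	0	1	1	0	0	0	0	0	1	1	1	0	0	1	1	1	1	1	1	1	1	1	0	0	1	0
Naegleria_fowleri	1	1	1	1	1	0	0	1	1	1	1	1	0	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0	0	0	1	1	1	0	1	0	0	0	0	0	0	0	1	1	0	0	0	0	0	1	1	1	0	0	1	1	1	1	1	1	1	1	1	0	0	1	0
Tsukubamonas_globosa	1	1	1	0	1	0	0	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	0	1	0	0	0	1	1	1	1	1	1	0	0	0	0	0	0	1	0	0	0	0	0	1	1	1	1	0	0	1	1	1	1	1	0	1	0	1	0	0	1	0
Andalucia_godoyi	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Histiona_aroides	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Jakoba_bahamiensis	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1
Jakoba_libera	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Reclinomonas_americana	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Seculamonas_ecuadoriensis	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
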