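((Andalucia_godoyi,(Histiona_aroides,Reclinomonas_americana),(Jakoba_bahamiensis,(Jakoba_libera,Seculamonas_ecuadoriensis))),(Tsukubamonas_globosa,(Acrasis_kona,(Naegleria_gruberi,Naegleria_fowleri))));
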