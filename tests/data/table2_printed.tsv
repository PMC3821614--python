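gene_symbol	genotype	p_value	enrichment
Ppp1r11	WT	0.00041	4.90
Pdcd5	WT	0.00412	4.78
Auh	WT	0.00822	4.26
Serf1	KO	0.00029	5.52
Gm4832	KO	0.00018	5.38
Dynlt3	KO	0.00361	5.18
Ccnh	KO	0.00072	5.03
Spp1	KO	0.00006	5.01
Uchl5	KO	0.00004	4.97
Mrps18c	KO	0.00002	4.84
Hspe1	KO	0.00008	4.83
Ndufa2	KO	0.00047	4.81
Tnfaip8	KO	0.00781	4.81
Etfa	KO	0.00035	4.76
Rps3a	KO	0.00271	4.66
Dazap2	KO	0.00008	4.53
Cfdp1	KO	0.00169	4.52
Rexo2	KO	0.00016	4.45
Naca	KO	0.00021	4.41
Gnpda2	KO	0.00008	4.34
1810022K09Rik	KO	0.00000	4.22
Auh	KO	0.00258	4.19
Hspa8	KO	0.00126	4.16
Cox20	KO	0.00121	4.04
Ppp1r11	KO	0.00287	4.01
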