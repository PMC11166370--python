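gene_id	description	ev3_lfc	ev3_p	ev6_lfc	ev6_p	hpc3_lfc	hpc3_p	hpc6_lfc	hpc6_p	ctx3_lfc	ctx3_p	ctx6_lfc	ctx6_p	clinical_trial
Itga2b	Integrin alpha-IIb	-1.3	0.0001	0.6	0.0253	-0.6	0.6532	-2.6	0.1829	-1.0	0.6799	0.2	0.9273	X
Tln1	Talin-1	-1.3	0.0000	0.6	0.0108	0.7	0.1953	1.0	0.0296	0.2	0.6959	0.2	0.7239	X
Flna	Filamin-A	-2.0	0.0000	0.5	0.0174	ND	ND	0.7	0.2041	-3.0	0.0191	3.4	0.0062	X
Itga6	Integrin alpha-6	-2.7	0.0005	1.1	0.0304	ND	ND	ND	ND	ND	ND	ND	ND	X
Tgm2	Protein-glutamine gamma-glutamyltransferase 2	-3.8	0.0000	4.3	0.0042	-0.6	0.6532	0.5	0.5584	0.0	0.9960	0.2	0.8745	X
Mup2	Major urinary protein 2	6.3	0.0000	4.0	0.0109	ND	ND	ND	ND	ND	ND	ND	ND	X
Orm2	Alpha-1-acid glycoprotein 2	4.3	0.0029	2.8	0.0335	ND	ND	ND	ND	ND	ND	ND	ND	X
Mug2	Murinoglobulin-2	ND	ND	6.7	0.0000	ND	ND	ND	ND	ND	ND	ND	ND	X
Flnc	Filamin C	ND	ND	4.6	0.0010	-1.0	0.6823	ND	ND	ND	ND	ND	ND	X
Pfkm	ATP-dependent 6-phosphofructokinase, muscle type	ND	ND	4.6	0.0010	0.0	0.8533	0.1	0.6199	0.0	0.7990	0.0	0.9104	X
Cryaa	Isoform 2 of alpha-crystallin A chain	ND	ND	4.4	0.0026	ND	ND	ND	ND	ND	ND	ND	ND	X
Hspa1l	Heat shock 70-kDa protein 1-like	ND	ND	4.0	0.0109	0.0	0.9405	0.2	0.3304	0.0	0.9587	-0.1	0.7915	X
Vdac1	Voltage-dependent anion-selective channel protein 1	ND	ND	4.0	0.0109	0.1	0.4452	-0.1	0.5607	0.0	0.8182	-0.2	0.1824	X
Ckm	Creatine kinase M-type	ND	ND	3.8	0.0177	-0.1	0.8240	0.4	0.5060	0.0	0.9887	0.2	0.8232	X
A2m	Alpha-2-macroglobulin-P	5.0	0.0001	ND	ND	ND	ND	ND	ND	ND	ND	ND	ND	X
Qsox1	Isoform 3 of sulfhydryl oxidase 1	4.3	0.0029	ND	ND	ND	ND	ND	ND	ND	ND	ND	ND	X
Hp	Haptoglobin	7.1	0.0000	ND	ND	1.0	0.6839	-2.6	0.0596	1.0	0.6863	-3.1	0.0765	O
H2-L	H-2 class I histocompatibility antigen, L-D alpha chain	4.3	0.0029	ND	ND	ND	ND	ND	ND	ND	ND	ND	ND	X
Pltp	Phospholipid transfer protein	3.5	0.0036	ND	ND	ND	ND	-1.0	0.6852	ND	ND	ND	ND	X
Man2b1	Lysosomal alpha-mannosidase	3.3	0.0057	ND	ND	ND	ND	ND	ND	ND	ND	ND	ND	X
Pf4	Platelet factor 4	2.4	0.0000	-3.2	0.0000	ND	ND	ND	ND	ND	ND	ND	ND	X
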