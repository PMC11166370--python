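stratum	protein_id	log2_fold
hippocampus_3mo	Capzb	6.2
hippocampus_3mo	Sh3glb2	-5.6
hippocampus_3mo	Tpp2	5.3
hippocampus_3mo	Eno3	5.8
hippocampus_3mo	Hpca	7.0
hippocampus_3mo	Syn2	-6.1
cortex_3mo	Capzb	5.9
cortex_3mo	Sh3glb2	-5.2
cortex_3mo	Tpp2	5.1
cortex_3mo	Eno3	6.4
cortex_3mo	Gap43	-5.4
cortex_3mo	Nefl	5.2
plasma_EV_3mo	Mup2	6.3
plasma_EV_3mo	Hp	7.1
plasma_EV_3mo	A2m	5.0
hippocampus_6mo	Gfap	6.6
hippocampus_6mo	Slc25a31	-5.1
hippocampus_6mo	Vim	5.9
cortex_6mo	Gfap	5.7
cortex_6mo	Slc25a31	-5.3
cortex_6mo	Aqp4	5.5
plasma_EV_6mo	Mug2	6.7
age_hippocampus	Tuba3b	5.4
age_hippocampus	Tpp2	5.2
age_hippocampus	Cadps2	-5.7
age_hippocampus	Atp4a	5.1
age_hippocampus	Sgip1	-6.2
age_hippocampus	Camk2a	5.3
age_cortex	Tuba3b	5.6
age_cortex	Tpp2	5.5
age_cortex	Cadps2	-5.3
age_cortex	Atp4a	6.0
age_cortex	Sgip1	-5.8
age_cortex	Dlg4	-5.2
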