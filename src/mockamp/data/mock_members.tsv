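name	genus	genome_size_bp	n_16s_copies	is_bacterial	copies_per_ug_reported
Campylobacter jejuni 11168	Campylobacter	1641481	3	1	5.64e8
Salmonella enterica serovar Typhimurium SL1344	Salmonella	4878012	6	1	1.89e8
Escherichia coli mg1655	Escherichia	4656144	7	1	1.99e8
Megasphaera elsdenii LC-1	Megasphaera	2474718	7	1	3.74e8
Cloacibacillus porcorum CL-84	Cloacibacillus	3585187	3	1	2.57e8
Brachyspira hyodysenteriae	Brachyspira	3050489	1	1	3.04e8
Haemophilus parasuis 29755	Haemophilus	2224137	2	1	4.17e8
Bordetella bronchiseptica 1289	Bordetella	5207899	3	1	1.78e8
Staphylococcus aureus USA300	Staphylococcus	2872915	5	1	3.22e8
Bacteroides thetaiotaomicron	Bacteroides	6293399	5	1	1.47e8
Faecalibacterium prausnitzii A2-165	Faecalibacterium	3080849	3	1	3.01e8
Streptococcus parasanguinis	Streptococcus	2153652	4	1	4.30e8
Parabacteroides merdae	Parabacteroides	4431877	3	1	2.09e8
Oscillibacter valericigenes	Oscillibacter	4470622	3	1	2.07e8
Desulfovibrio gigas	Desulfovibrio	3788225	4	1	2.45e8
Lactobacillus delbrueckii subspecies bulgaricus	Lactobacillus	1864998	9	1	4.97e8
Coriobacterium glomerans	Coriobacterium	2115681	2	1	4.38e8
Oxalobacter formigenes BA-2	Oxalobacter	2509362	1	1	3.69e8
Roseburia hominis A2-183	Roseburia	3592125	4	1	2.58e8
Methanobrevibacter smithii	Methanobrevibacter	1704865	1	0	5.43e8
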