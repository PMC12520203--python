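# Transformation rules for aripiprazole suspect enumeration (see rules_haloperidol.tsv).
label	add	remove	category	elementary
hydroxylation	O	-	d	1
oxidation	O	H2	d	1
dehydrogenation	-	H2	d	1
hydrogenation	H2	-	d	1
chlorine_to_hydroxyl	HO	Cl	b	1
tetrahydropyrazine_formation	-	C13H17NO2	a	0
quinolinone_loss	-	C9H9NO2	a	0
quinolinone_ring_cleavage	-	C7H7N	a	0
dichlorophenylpiperazine_loss	-	C10H12Cl2N2	b	0
piperazine_ring_cleavage	-	C2H2	c	0
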