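# Haloperidol transformation-product registry (TiO2 photocatalysis, positive mode).
# Categories: a = hydroxylation with structure loss, b = hydroxylation with Cl loss,
# c = hydroxylation with F loss, d = hydroxylation.
# cation_formula is the [M+H]+ formula; isomers are letters in elution order, with
# a retention time (min) after '@' where one was published.  described=0 marks masses
# listed without a structural description; they are excluded from the default registry.
name	cation_formula	observed_mz	category	isomers	described	note
TP_ha_286	C14H21ClNO3	286.1186	a	A	1	side-chain cleavage (fluorophenyl ketone loss) with two hydroxylations
TP_ha_298	C15H21ClNO3	298.1200	a	A	1	side-chain hydroxylation plus oxidation; chlorophenyl-hydroxypiperidine intact
TP_ha_314	C15H21ClNO4	314.1132	a	A,B,C,D,E,F	1	six isomers; A and C peak only after 60 min
TP_ha_358	C21H25FNO3	358.1795	b	A	1	chlorine replaced by hydroxyl
TP_ha_362	C20H25FNO4	362.1746	b	A	1	quaternary amine; ring-opened after Cl substitution
TP_ha_378	-	378.1696	b	A	0	listed mass without structural description
TP_ha_388	C21H23FNO5	388.1544	b	A,B	1	two hydroxylations plus oxidation on hydroxy-phenylpiperidine moiety
TP_ha_390	C21H25FNO5	390.1700	b	A,B	1	triple hydroxylation (A: all on benzene ring)
TP_ha_406	C21H25FNO6	406.1638	b	A,B	1	four hydroxylations
TP_ha_374	C21H25ClNO3	374.1503	c	A	1	fluorine replaced by hydroxyl
TP_ha_392	C21H24ClFNO3	392.1416	d	A@18.45,B,C,D	1	single hydroxylation; B is a resolved minor shoulder after A
TP_ha_408	C21H24ClFNO4	408.1358	d	A,B,C,D	1	double hydroxylation
TP_ha_410	C21H26ClFNO4	410.1515	d	A,B,C,D,E	1	double hydroxylation plus ketone reduction
TP_ha_422	C21H22ClFNO5	422.1156	d	A	1	triple hydroxylation plus dehydrogenation
TP_ha_424	C21H24ClFNO5	424.1304	d	A	1	triple hydroxylation (hydrogenated TP_ha_422)
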