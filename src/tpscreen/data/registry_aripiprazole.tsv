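# Aripiprazole transformation-product registry (TiO2 photocatalysis, positive mode).
# Categories: a = modification/loss of the tetrahydroquinolone ring, b = modification/loss
# of the dichlorobenzene ring, c = modification of the piperazine ring, d = generic changes.
# TP_ar_229 was published as [C10H11Cl2N]+ but that composition's cation mass is ~215.03;
# the two-nitrogen formula implied by the proposed dichlorophenyl-tetrahydropyrazine
# structure is stored instead (note field keeps the published text).
name	cation_formula	observed_mz	category	isomers	described	note
TP_ar_229	C10H11Cl2N2	229.0284	a	A	1	published formula [C10H11Cl2N]+ inconsistent with its mass; stored with two nitrogens
TP_ar_231	C10H13Cl2N2	231.0444	a	A	1	dehydrogenation of piperazine ring; radical Cl loss gives m/z 153.0340 (unassigned)
TP_ar_301	C14H19Cl2N2O	301.0864	a	A	1	quinolinone loss with side-chain oxidation
TP_ar_303	C14H21Cl2N2O	303.1018	a	A	1	ketone/aldehyde reduced to hydroxyl
TP_ar_317	C14H19Cl2N2O2	317.0811	a	A	1	two hydroxylations (one followed by oxidation) on the side chain
TP_ar_319	-	319.0960	a	A	0	listed mass without structural description
TP_ar_375	C16H21Cl2N2O4	375.0865	a	A	1	quinolinone ring cleavage plus three hydroxylations
TP_ar_234	C13H16NO3	234.1116	b	A	1	single hydroxylation; no Cl isotope pattern
TP_ar_252	C13H18NO4	252.1220	b	A	1	double hydroxylation; no Cl isotope pattern
TP_ar_422	C21H26Cl2N3O2	422.1400	c	A	1	piperazine ring cleavage
TP_ar_438	C21H26Cl2N3O3	438.1347	c	A	1	piperazine ring cleavage with hydroxylation
TP_ar_462	C23H26Cl2N3O3	462.1346	d	A	1	butyl-chain hydroxylation followed by reduction
TP_ar_464	C23H28Cl2N3O3	464.1502	d	A,B	1	single hydroxylation; two isomers
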