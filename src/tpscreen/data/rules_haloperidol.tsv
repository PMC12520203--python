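# Transformation rules for haloperidol suspect enumeration.
# add/remove are Hill formulas applied to the NEUTRAL parent ('-' = none).
# elementary=1 rules may repeat and combine freely; elementary=0 rules are
# single cleavage deltas usable at most once per chain.
label	add	remove	category	elementary
hydroxylation	O	-	d	1
oxidation	O	H2	d	1
dehydrogenation	-	H2	d	1
hydrogenation	H2	-	d	1
chlorine_to_hydroxyl	HO	Cl	b	1
fluorine_to_hydroxyl	HO	F	c	1
fluorophenyl_ketone_cleavage	O	C7H3F	a	0
side_chain_cleavage	O	C6H3F	a	0
ring_opening_with_cl_loss	HO2	CCl	b	0
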