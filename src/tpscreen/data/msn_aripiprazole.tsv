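# Reference MSn fragmentation of aripiprazole ([M+H]+ C23H28Cl2N3O2, observed 448.1565, rt 26.74 min).
# Columns as in msn_haloperidol.tsv.  Two published loss brackets do not close
# against their precursor formulas (printed_loss column); the stored loss_formula
# is the closure-consistent one implied by the published fragment formulas.
ms_level	precursor_formula	fragment_formula	observed_mz	abundance_pct	loss_formula	printed_dppm	printed_loss	radical
1	-	C23H28Cl2N3O2	448.1565	100	-	2.7	-	0
2	C23H28Cl2N3O2	C14H19Cl2N2	285.0930	100	C9H9NO2	3.6	-	0
2	C23H28Cl2N3O2	C13H16NO2	218.1180	9.3	C10H12Cl2N2	2.0	-	0
2	C23H28Cl2N3O2	C10H10NO2	176.0709	4.8	C13H18Cl2N2	1.7	C13H16Cl2N2	0
2	C23H28Cl2N3O2	C9H10NO	148.0759	0.7	C14H18Cl2N2O	1.4	-	0
3	C14H19Cl2N2	C10H12Cl2N	216.0346	50	C4H7N	2.2	-	0
3	C14H19Cl2N2	C6H12N	98.0961	100	C8H7Cl2N	-3.3	-	0
3	C13H16NO2	C10H10NO2	176.0709	4.8	C3H6	1.7	-	0
3	C13H16NO2	C9H10NO2	164.0708	4.8	C4H6	1.2	-	0
3	C13H16NO2	C9H10NO	148.0759	0.7	C4H6O	1.4	-	0
3	C10H10NO2	C9H10NO	148.0759	100	CO	1.4	-	0
3	C10H10NO2	C8H10N	120.0808	8	C2O2	0.2	2CO	0
3	C10H10NO2	C6H8N	94.0651	1	C4H2O2	-0.3	C2H2O2	0
3	C9H10NO	C8H10N	120.0808	100	CO	0.2	-	0
3	C9H10NO	C6H8N	94.0651	4	C3H2O	-0.3	-	0
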