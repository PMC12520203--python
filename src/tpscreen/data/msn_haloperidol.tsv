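# Reference MSn fragmentation of haloperidol ([M+H]+ C21H24ClFNO2, observed 376.1466, rt 21.35 min).
# Columns: ms_level, precursor_formula, fragment_formula, observed_mz, abundance_pct, loss_formula, printed_dppm, printed_loss, radical
# loss_formula always closes (fragment + loss = precursor); printed_loss records the
# published bracket text where it differs from the closure-consistent formula.
ms_level	precursor_formula	fragment_formula	observed_mz	abundance_pct	loss_formula	printed_dppm	printed_loss	radical
1	-	C21H24ClFNO2	376.1466	100	-	-2.2	-	0
2	C21H24ClFNO2	C21H22ClFNO	358.1363	59	H2O	-1.5	-	0
2	C21H24ClFNO2	C11H15ClNO	212.0834	0.6	C10H9FO	-1.3	-	0
2	C21H24ClFNO2	C12H13FNO	206.0972	0.5	C9H11ClO	-1.8	-	0
2	C21H24ClFNO2	C11H13FNO	194.0973	2	C10H11ClO	-1.4	-	0
2	C21H24ClFNO2	C10H10FO	165.0712	100	C11H14ClNO	1.1	-	0
2	C21H24ClFNO2	C7H4FO	123.0242	22	C14H20ClNO	1.1	-	0
2	C21H24ClFNO2	C6H4F	95.0296	0.1	C15H20ClNO2	4.7	-	0
3	C21H22ClFNO	C11H13ClN	194.0728	5	C10H9FO	-1.6	C10H9FO	0
3	C11H13FNO	C10H10FO	165.0712	100	CH3N	1.1	-	0
3	C10H10FO	C7H4FO	123.0242	100	C3H6	1.1	-	0
3	C7H4FO	C6H4F	95.0296	0.1	CO	4.7	-	0
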