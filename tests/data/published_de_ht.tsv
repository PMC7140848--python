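mirna	kind	count0_6h	count6h	lfc_6h	p_6h	count0_12h	count12h	lfc_12h	p_12h
novel_mir27	novel	155	47	-1.71	3.28e-5	155	0	-17.23	6.96e-41
novel_mir95	novel	29	0	-14.8	1.89e-6	29	0	-14.77	3.32e-8
novel_mir149	novel	143	0	-17.1	2.41e-29	143	29	-2.25	7.67e-15
novel_mir46	novel					0	15	13.66	5.58e-6
novel_mir89	novel					107	0	-16.62	1.96e-28
novel_mir105	novel					85	0	-16.29	9.93e-23
novel_mir114	novel					20	0	-14.29	7.16e-6
novel_mir120	novel					79	21	-1.85	6.84e-7
novel_mir177	novel	0	13	13.55	1.82e-6
novel_mir238	novel					241	0	-17.86	3.46e-63
novel_mir240	novel					17	0	-14.05	4.29e-5
novel_mir243	novel					0	20	14.21	1.03e-7
novel_mir250	novel					104	0	-16.67	1.17e-27
novel_mir255	novel	1494	494	-1.67	5.79e-31
bra-miR156e-3p	known					1971	696	-1.51	6.29e-90
bra-miR824	known	1026	396	-1.39	2.77e-13	1026	261	-2.01	7.86e-77
bra-miR1885a	known	1271	396	-1.68	4.82e-31
bra-miR1885b	known	1546	572	-1.42	1.63e-22
bra-miR172d-5p	known					1	14	3.70	0.00011
bra-miR400-5p	known	750	231	-1.7	1.77e-19
bra-miR396-3p	known	1694	693	-1.29	2.00e-16
bra-miR391-5p	known	335	110	-1.59	3.48e-8
bra-miR2111b-3p	known	30	1	-4.75	1.48e-5	30	0	-14.72	1.82e-8
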