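probe_id	chromosome	gene	gene_region	island_region	ngt_myoblast_mean	ngt_myoblast_sd	ngt_myotube_mean	ngt_myotube_sd	ngt_difference	ngt_p	ngt_q	t2d_myoblast_mean	t2d_myoblast_sd	t2d_myotube_mean	t2d_myotube_sd	t2d_difference	t2d_p	t2d_q
cg05133314	1	GPR153	TSS1500	S_Shore	11.0	1.0	10.0	1.0	-1.0	0.0040	0.0427	10.6	1.3	12.6	2.9	2.0	0.0107	0.0432
cg09158487	12	HNRNPA1; HNRPA1L-2; CBX5	TSS1500; TSS1500; TSS200	Island	8.4	0.6	7.8	0.6	-0.6	0.0031	0.0376	7.5	1.0	8.3	0.6	0.9	0.0052	0.0267
cg10245072	4	TLR6	3'UTR		87.7	2.9	84.2	3.1	-3.5	0.0031	0.0376	87.5	2.5	88.6	2.3	1.1	0.0012	0.0110
cg10389371	15	AKAP13	5'UTR		90.4	3.4	88.8	3.6	-1.5	0.0040	0.0427	89.7	5.6	91.4	3.8	1.7	0.0085	0.0369
cg14059340	17	C17orf97	1stExon	Island	6.5	0.7	5.7	0.6	-0.8	0.0017	0.0294	6.0	0.6	6.7	0.6	0.7	0.0031	0.0189
cg15622783	6	NT5DC1	TSS200	Island	3.2	0.4	2.9	0.3	-0.4	0.0052	0.0482	3.0	0.2	3.2	0.2	0.2	0.0052	0.0267
cg20188676	12				67.5	3.3	62.3	3.9	-5.2	0.0009	0.0229	67.6	10.3	72.6	9.0	5.0	0.0012	0.0110
cg00428492	3	GTPBP8	TSS1500	N_Shore	95.7	0.8	96.5	0.7	0.8	0.0031	0.0376	96.2	0.8	95.6	0.7	-0.6	0.0067	0.0314
cg00549566	7	ELMO1	5'UTR	Island	6.8	0.5	7.9	0.9	1.1	0.0017	0.0294	7.5	1.5	6.7	1.2	-0.8	0.0023	0.0159
cg01195526	2	SP110	TSS1500		79.4	1.6	83.6	3.4	4.2	0.0006	0.0205	83.3	2.9	81.4	3.6	-1.9	0.0067	0.0314
cg01941585	12	HMGA2	Body		96.1	0.7	97.0	0.5	0.9	0.0006	0.0205	95.9	1.1	94.9	2.1	-1.1	0.0107	0.0432
cg04406574	8	MYST3	TSS1500	S_Shore	87.3	8.5	90.1	6.2	2.8	0.0017	0.0294	91.2	2.4	87.8	3.1	-3.4	0.0031	0.0189
cg04459360	6			N_Shelf	87.4	4.0	90.0	2.4	2.7	0.0009	0.0229	90.9	2.9	88.3	3.9	-2.6	0.0052	0.0267
cg04568923	17	COX10	Body	Island	93.1	2.7	95.2	1.3	2.1	0.0040	0.0427	95.2	1.8	91.9	5.8	-3.2	0.0052	0.0267
cg04977002	13	UPF3A; UPF3A	1stExon; 1stExon	Island	5.6	0.4	6.6	0.5	0.9	0.0006	0.0205	6.2	1.0	5.6	1.0	-0.6	0.0067	0.0314
cg05076820	7	LOC100124692	Body		24.6	8.2	28.2	8.7	3.5	0.0040	0.0427	25.5	8.4	21.1	6.0	-4.3	0.0067	0.0314
cg05221370	7	LRRN3; IMMP2L	5'UTR; Body		41.1	10.0	46.9	10.1	5.8	0.0009	0.0229	41.8	12.7	37.9	12.2	-3.9	0.0085	0.0369
cg07203362	2				61.8	12.2	68.6	12.3	6.7	0.0052	0.0482	68.1	19.4	64.4	20.8	-3.7	0.0085	0.0369
cg08638395	1	XPR1	TSS200	Island	3.1	0.5	3.6	0.3	0.5	0.0023	0.0334	3.4	0.2	3.1	0.2	-0.2	0.0040	0.0225
cg09180070	8				72.0	9.0	77.0	6.7	5.0	0.0002	0.0161	72.2	28.5	67.3	31.5	-4.9	0.0002	0.0049
cg09291982	3	ZBTB20	Body	Island	96.8	0.6	97.5	0.4	0.7	0.0031	0.0376	97.8	0.7	96.7	1.4	-1.0	0.0067	0.0314
cg12076823	11	RPS6KA4	Body	S_Shore	83.5	7.1	85.9	6.1	2.4	0.0031	0.0376	87.2	1.9	85.3	2.4	-1.9	0.0085	0.0369
cg12891678	1				40.7	14.0	44.0	12.2	3.3	0.0023	0.0334	46.0	10.8	40.8	9.7	-5.2	0.0012	0.0110
cg13044475	13	THSD1	Body	N_Shelf	93.0	0.6	94.3	1.1	1.3	0.0017	0.0294	94.2	1.9	92.9	1.9	-1.3	0.0085	0.0369
cg13186228	20	STX16	TSS1500	Island	14.1	2.8	17.2	4.2	3.0	0.0052	0.0482	21.3	14.9	18.4	14.2	-2.8	0.0067	0.0314
cg13454978	8				37.2	15.6	41.6	16.8	4.5	0.0052	0.0482	44.9	27.9	41.9	27.2	-2.9	0.0052	0.0267
cg13474639	9	MRPL50; ZNF189	Body; TSS1500	N_Shore	27.9	13.0	32.3	13.1	4.4	0.0040	0.0427	30.9	8.5	25.5	5.7	-5.4	0.0052	0.0267
cg13633560	11	LRRC32; LRRC32	5'UTR; 1stExon	N_Shore	13.4	6.7	15.9	7.8	2.5	0.0004	0.0178	15.4	9.8	12.3	8.3	-3.1	0.0052	0.0267
cg14299369	15	TGM5	TSS1500		84.6	5.2	86.8	5.1	2.2	0.0006	0.0205	87.7	2.3	83.9	1.9	-3.8	0.0004	0.0059
cg15935791	1	LOC10030240; RASAL2	Body; TSS1500	N_Shore	6.0	0.9	6.6	0.7	0.6	0.0023	0.0334	6.8	0.9	6.0	0.7	-0.8	0.0107	0.0432
cg15948245	7				67.7	1.2	68.9	1.4	1.1	0.0009	0.0229	70.2	2.4	68.7	2.0	-1.5	0.0067	0.0314
cg18863090	1	DAB1	5'UTR	N_Shore	31.9	16.5	35.8	17.4	3.9	0.0040	0.0427	36.3	18.5	30.3	18.7	-6.0	0.0023	0.0159
cg20574381	11	ST5	Body	S_Shelf	85.8	4.0	88.3	3.9	2.5	0.0017	0.0294	83.4	6.8	79.2	9.0	-4.3	0.0107	0.0432
cg20998885	20	C20orf79	1stExon		90.0	2.6	91.5	2.2	1.5	0.0012	0.0260	92.5	1.4	90.7	1.7	-1.8	0.0067	0.0314
cg21391046	4				85.5	7.6	88.8	6.2	3.4	0.0009	0.0229	87.2	5.8	84.0	8.0	-3.2	0.0085	0.0369
cg21889054	14	NUMB	5'UTR		88.1	4.3	91.1	3.0	2.9	0.0009	0.0229	92.0	3.3	90.2	3.3	-1.8	0.0031	0.0189
cg23763197	11	H2AFX; H2AFX	3'UTR; 1stExon	Island	4.3	0.2	4.9	0.4	0.6	0.0017	0.0294	5.3	0.8	4.4	0.6	-1.0	0.0012	0.0110
cg27294837	13	POU4F1	TSS1500	S_Shore	54.6	21.2	60.8	18.7	6.2	0.0012	0.0260	56.5	28.8	50.2	29.9	-6.3	0.0067	0.0314
cg27559724	3	RFC4; RFC4	TSS200; TSS1500	Island	21.4	8.6	23.5	8.7	2.1	0.0052	0.0482	23.5	9.4	21.4	9.2	-2.0	0.0004	0.0059
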