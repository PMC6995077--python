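kind	position	rna_base	dna_base	pam	penalty
mm	1	A	C	.	0.45
mm	1	A	G	.	0.6
mm	1	A	T	.	0.3
mm	1	C	A	.	0.5
mm	1	C	G	.	0.3
mm	1	C	T	.	0.55
mm	1	G	A	.	1.0
mm	1	G	C	.	0.35
mm	1	G	T	.	0.4
mm	1	U	A	.	0.45
mm	1	U	C	.	1.0
mm	1	U	G	.	0.5
mm	2	A	C	.	0.4311
mm	2	A	G	.	0.5747
mm	2	A	T	.	0.2874
mm	2	C	A	.	0.4789
mm	2	C	G	.	0.2874
mm	2	C	T	.	0.5268
mm	2	G	A	.	1.0
mm	2	G	C	.	0.3353
mm	2	G	T	.	0.3832
mm	2	U	A	.	0.4311
mm	2	U	C	.	0.7663
mm	2	U	G	.	0.4789
mm	3	A	C	.	0.4121
mm	3	A	G	.	0.5495
mm	3	A	T	.	0.2747
mm	3	C	A	.	0.4579
mm	3	C	G	.	0.2747
mm	3	C	T	.	0.5037
mm	3	G	A	.	0.8242
mm	3	G	C	.	0.3205
mm	3	G	T	.	0.3663
mm	3	U	A	.	0.4121
mm	3	U	C	.	0.7326
mm	3	U	G	.	0.4579
mm	4	A	C	.	0.3932
mm	4	A	G	.	0.5242
mm	4	A	T	.	0.2621
mm	4	C	A	.	0.4368
mm	4	C	G	.	0.2621
mm	4	C	T	.	0.4805
mm	4	G	A	.	0.7863
mm	4	G	C	.	0.3058
mm	4	G	T	.	0.3495
mm	4	U	A	.	0.3932
mm	4	U	C	.	0.6989
mm	4	U	G	.	0.4368
mm	5	A	C	.	0.3742
mm	5	A	G	.	0.4989
mm	5	A	T	.	0.2495
mm	5	C	A	.	0.4158
mm	5	C	G	.	0.2495
mm	5	C	T	.	0.4574
mm	5	G	A	.	0.7484
mm	5	G	C	.	0.2911
mm	5	G	T	.	0.3326
mm	5	U	A	.	0.3742
mm	5	U	C	.	0.6653
mm	5	U	G	.	0.4158
mm	6	A	C	.	0.3553
mm	6	A	G	.	0.4737
mm	6	A	T	.	0.2368
mm	6	C	A	.	0.3947
mm	6	C	G	.	0.2368
mm	6	C	T	.	0.4342
mm	6	G	A	.	0.7105
mm	6	G	C	.	0.2763
mm	6	G	T	.	0.3158
mm	6	U	A	.	0.3553
mm	6	U	C	.	0.6316
mm	6	U	G	.	0.3947
mm	7	A	C	.	0.3363
mm	7	A	G	.	0.4484
mm	7	A	T	.	0.2242
mm	7	C	A	.	0.3737
mm	7	C	G	.	0.2242
mm	7	C	T	.	0.4111
mm	7	G	A	.	0.6726
mm	7	G	C	.	0.2616
mm	7	G	T	.	0.2989
mm	7	U	A	.	0.3363
mm	7	U	C	.	0.5979
mm	7	U	G	.	0.3737
mm	8	A	C	.	0.3174
mm	8	A	G	.	0.4232
mm	8	A	T	.	0.2116
mm	8	C	A	.	0.3526
mm	8	C	G	.	0.2116
mm	8	C	T	.	0.3879
mm	8	G	A	.	0.6347
mm	8	G	C	.	0.2468
mm	8	G	T	.	0.2821
mm	8	U	A	.	0.3174
mm	8	U	C	.	0.5642
mm	8	U	G	.	0.3526
mm	9	A	C	.	0.2984
mm	9	A	G	.	0.3979
mm	9	A	T	.	0.1989
mm	9	C	A	.	0.3316
mm	9	C	G	.	0.1989
mm	9	C	T	.	0.3647
mm	9	G	A	.	0.5968
mm	9	G	C	.	0.2321
mm	9	G	T	.	0.2653
mm	9	U	A	.	0.2984
mm	9	U	C	.	0.5305
mm	9	U	G	.	0.3316
mm	10	A	C	.	0.2795
mm	10	A	G	.	0.3726
mm	10	A	T	.	0.1863
mm	10	C	A	.	0.3105
mm	10	C	G	.	0.1863
mm	10	C	T	.	0.3416
mm	10	G	A	.	0.5589
mm	10	G	C	.	0.2174
mm	10	G	T	.	0.2484
mm	10	U	A	.	0.2795
mm	10	U	C	.	0.4968
mm	10	U	G	.	0.3105
mm	11	A	C	.	0.2605
mm	11	A	G	.	0.3474
mm	11	A	T	.	0.1737
mm	11	C	A	.	0.2895
mm	11	C	G	.	0.1737
mm	11	C	T	.	0.3184
mm	11	G	A	.	0.5211
mm	11	G	C	.	0.2026
mm	11	G	T	.	0.2316
mm	11	U	A	.	0.2605
mm	11	U	C	.	0.4632
mm	11	U	G	.	0.2895
mm	12	A	C	.	0.2416
mm	12	A	G	.	0.3221
mm	12	A	T	.	0.1611
mm	12	C	A	.	0.2684
mm	12	C	G	.	0.1611
mm	12	C	T	.	0.2953
mm	12	G	A	.	0.4832
mm	12	G	C	.	0.1879
mm	12	G	T	.	0.2147
mm	12	U	A	.	0.2416
mm	12	U	C	.	0.4295
mm	12	U	G	.	0.2684
mm	13	A	C	.	0.2226
mm	13	A	G	.	0.2968
mm	13	A	T	.	0.1484
mm	13	C	A	.	0.2474
mm	13	C	G	.	0.1484
mm	13	C	T	.	0.2721
mm	13	G	A	.	0.4453
mm	13	G	C	.	0.1732
mm	13	G	T	.	0.1979
mm	13	U	A	.	0.2226
mm	13	U	C	.	0.3958
mm	13	U	G	.	0.2474
mm	14	A	C	.	0.2037
mm	14	A	G	.	0.2716
mm	14	A	T	.	0.1358
mm	14	C	A	.	0.2263
mm	14	C	G	.	0.1358
mm	14	C	T	.	0.2489
mm	14	G	A	.	0.4074
mm	14	G	C	.	0.1584
mm	14	G	T	.	0.1811
mm	14	U	A	.	0.2037
mm	14	U	C	.	0.3621
mm	14	U	G	.	0.2263
mm	15	A	C	.	0.1847
mm	15	A	G	.	0.2463
mm	15	A	T	.	0.1232
mm	15	C	A	.	0.2053
mm	15	C	G	.	0.1232
mm	15	C	T	.	0.2258
mm	15	G	A	.	0.3695
mm	15	G	C	.	0.1437
mm	15	G	T	.	0.1642
mm	15	U	A	.	0.1847
mm	15	U	C	.	0.3284
mm	15	U	G	.	0.2053
mm	16	A	C	.	0.1658
mm	16	A	G	.	0.2211
mm	16	A	T	.	0.1105
mm	16	C	A	.	0.1842
mm	16	C	G	.	0.1105
mm	16	C	T	.	0.2026
mm	16	G	A	.	0.3316
mm	16	G	C	.	0.1289
mm	16	G	T	.	0.1474
mm	16	U	A	.	0.1658
mm	16	U	C	.	0.2947
mm	16	U	G	.	0.1842
mm	17	A	C	.	0.1468
mm	17	A	G	.	0.1958
mm	17	A	T	.	0.0979
mm	17	C	A	.	0.1632
mm	17	C	G	.	0.0979
mm	17	C	T	.	0.1795
mm	17	G	A	.	0.2937
mm	17	G	C	.	0.1142
mm	17	G	T	.	0.1305
mm	17	U	A	.	0.1468
mm	17	U	C	.	0.2611
mm	17	U	G	.	0.1632
mm	18	A	C	.	0.1279
mm	18	A	G	.	0.1705
mm	18	A	T	.	0.0853
mm	18	C	A	.	0.1421
mm	18	C	G	.	0.0853
mm	18	C	T	.	0.1563
mm	18	G	A	.	0.2558
mm	18	G	C	.	0.0995
mm	18	G	T	.	0.1137
mm	18	U	A	.	0.1279
mm	18	U	C	.	0.2274
mm	18	U	G	.	0.1421
mm	19	A	C	.	0.1089
mm	19	A	G	.	0.1453
mm	19	A	T	.	0.0726
mm	19	C	A	.	0.1211
mm	19	C	G	.	0.0726
mm	19	C	T	.	0.1332
mm	19	G	A	.	0.2179
mm	19	G	C	.	0.0847
mm	19	G	T	.	0.0968
mm	19	U	A	.	0.1089
mm	19	U	C	.	0.1937
mm	19	U	G	.	0.1211
mm	20	A	C	.	0.09
mm	20	A	G	.	0.12
mm	20	A	T	.	0.06
mm	20	C	A	.	0.1
mm	20	C	G	.	0.06
mm	20	C	T	.	0.11
mm	20	G	A	.	0.18
mm	20	G	C	.	0.07
mm	20	G	T	.	0.08
mm	20	U	A	.	0.09
mm	20	U	C	.	0.16
mm	20	U	G	.	0.1
pam	.	.	.	AA	0.0
pam	.	.	.	AC	0.0
pam	.	.	.	AG	0.26
pam	.	.	.	AT	0.0
pam	.	.	.	CA	0.0
pam	.	.	.	CC	0.0
pam	.	.	.	CG	0.11
pam	.	.	.	CT	0.0
pam	.	.	.	GA	0.07
pam	.	.	.	GC	0.02
pam	.	.	.	GG	1.0
pam	.	.	.	GT	0.02
pam	.	.	.	TA	0.0
pam	.	.	.	TC	0.0
pam	.	.	.	TG	0.04
pam	.	.	.	TT	0.0
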