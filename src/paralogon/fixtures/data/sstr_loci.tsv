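# Somatostatin receptor (SSTR) gene locations across vertebrate genomes,
# from the published repertoire survey (point positions stored as 1-bp loci;
# Mb/Kb positions converted exactly: 38.68 Mb -> 38680000 bp).
# The anole lizard SSTR1 entry carries no printed location and is omitted.
species	chromosome	start	end	strand	gene_id	family_id	subtype_label
human	14	38680000	38680001	.	SSTR1	SSTR	SSTR1
human	17	71160000	71160001	.	SSTR2	SSTR	SSTR2
human	22	37600000	37600001	.	SSTR3	SSTR	SSTR3
human	20	23020000	23020001	.	SSTR4	SSTR	SSTR4
human	16	1120000	1120001	.	SSTR5	SSTR	SSTR5
mouse	12	59310000	59310001	.	SSTR1	SSTR	SSTR1
mouse	11	113480000	113480001	.	SSTR2	SSTR	SSTR2
mouse	15	78370000	78370001	.	SSTR3	SSTR	SSTR3
mouse	2	148220000	148220001	.	SSTR4	SSTR	SSTR4
mouse	17	25630000	25630001	.	SSTR5	SSTR	SSTR5
dog	8	19580000	19580001	.	SSTR1	SSTR	SSTR1
dog	9	10000000	10000001	.	SSTR2	SSTR	SSTR2
dog	10	30400000	30400001	.	SSTR3	SSTR	SSTR3
dog	6	42650000	42650001	.	SSTR5	SSTR	SSTR5
opossum	1	278650000	278650001	.	SSTR1	SSTR	SSTR1
opossum	2	217490000	217490001	.	SSTR2	SSTR	SSTR2
opossum	8	91980000	91980001	.	SSTR3	SSTR	SSTR3
opossum	1	598180000	598180001	.	SSTR4	SSTR	SSTR4
opossum	6	153470	153471	.	SSTR5	SSTR	SSTR5
chicken	5	39750000	39750001	.	SSTR1	SSTR	SSTR1
chicken	18	9000000	9000001	.	SSTR2	SSTR	SSTR2
chicken	1	53390000	53390001	.	SSTR3	SSTR	SSTR3
chicken	3	3270000	3270001	.	SSTR4	SSTR	SSTR4
chicken	14	5640000	5640001	.	SSTR5	SSTR	SSTR5
anole	2	96750000	96750001	.	SSTR2	SSTR	SSTR2
anole	5	22840000	22840001	.	SSTR3	SSTR	SSTR3
anole	GL343263.1	1760000	1760001	.	SSTR5	SSTR	SSTR5
frog	GL172781.1	1070000	1070001	.	SSTR1	SSTR	SSTR1
frog	GL172812.1	1790000	1790001	.	SSTR2	SSTR	SSTR2
frog	GL172724.1	1410000	1410001	.	SSTR3	SSTR	SSTR3
frog	GL172884.1	512430	512431	.	SSTR4	SSTR	SSTR4
frog	GL172659.1	446170	446171	.	SSTR5	SSTR	SSTR5
coelacanth	JH126598.1	530000	530001	.	SSTR1	SSTR	SSTR1
coelacanth	JH126581.1	3450000	3450001	.	SSTR2	SSTR	SSTR2
coelacanth	JH129649.1	210000	210001	.	SSTR3	SSTR	SSTR3
coelacanth	JH126648.1	2610000	2610001	.	SSTR4	SSTR	SSTR4
coelacanth	JH129247.1	210000	210001	.	SSTR5	SSTR	SSTR5
coelacanth	JH127490.1	260000	260001	.	SSTR6	SSTR	SSTR6
coelacanth	JH126581.1	3470000	3470001	.	SSTRX	SSTR	SSTRX
gar	LG7	4440000	4440001	.	SSTR1	SSTR	SSTR1
gar	LG10	34840000	34840001	.	SSTR2	SSTR	SSTR2
gar	LG12	34190000	34190001	.	SSTR3	SSTR	SSTR3
gar	LG13	4690000	4690001	.	SSTR5	SSTR	SSTR5
gar	LG28	1080000	1080001	.	SSTR6	SSTR	SSTR6
zebrafish	17	10350000	10350001	.	SSTR1	SSTR	SSTR1
zebrafish	3	63080000	63080001	.	SSTR2a	SSTR	SSTR2a
zebrafish	12	1730000	1730001	.	SSTR2b	SSTR	SSTR2b
zebrafish	3	29750000	29750001	.	SSTR3a	SSTR	SSTR3a
zebrafish	Zv9_NA631	3420	3421	.	SSTR3b	SSTR	SSTR3b
zebrafish	24	16780000	16780001	.	SSTR5a	SSTR	SSTR5a
zebrafish	1	55010000	55010001	.	SSTR5b	SSTR	SSTR5b
zebrafish	7	19630000	19630001	.	SSTR6	SSTR	SSTR6
stickleback	groupXI	9500000	9500001	.	SSTR2a	SSTR	SSTR2a
stickleback	groupV	6810000	6810001	.	SSTR2b	SSTR	SSTR2b
stickleback	groupXI	15590000	15590001	.	SSTR3a	SSTR	SSTR3a
stickleback	groupXI	11720000	11720001	.	SSTR5a	SSTR	SSTR5a
stickleback	groupIX	14950000	14950001	.	SSTR5b	SSTR	SSTR5b
stickleback	scaffold_47	436210	436211	.	SSTR6	SSTR	SSTR6
medaka	8	10930000	10930001	.	SSTR2a	SSTR	SSTR2a
medaka	scaffold5841	160	161	.	SSTR2b	SSTR	SSTR2b
medaka	8	2800000	2800001	.	SSTR3a	SSTR	SSTR3a
medaka	1	29100000	29100001	.	SSTR3b	SSTR	SSTR3b
medaka	8	13750000	13750001	.	SSTR5a	SSTR	SSTR5a
green_puffer	3	10440000	10440001	.	SSTR2a	SSTR	SSTR2a
green_puffer	2	4830000	4830001	.	SSTR2b	SSTR	SSTR2b
green_puffer	3	15060000	15060001	.	SSTR3a	SSTR	SSTR3a
green_puffer	18	10390000	10390001	.	SSTR3b	SSTR	SSTR3b
green_puffer	Un_random	59490000	59490001	.	SSTR3c	SSTR	SSTR3c
green_puffer	18	2400000	2400001	.	SSTR5b	SSTR	SSTR5b
fugu	scaffold_115	411360	411361	.	SSTR2a	SSTR	SSTR2a
fugu	scaffold_3	3770	3771	.	SSTR2b	SSTR	SSTR2b
fugu	scaffold_359	200560	200561	.	SSTR3a	SSTR	SSTR3a
fugu	scaffold_407	33360	33361	.	SSTR3b	SSTR	SSTR3b
fugu	scaffold_189	267650	267651	.	SSTR5b	SSTR	SSTR5b
fugu	scaffold_164	38740	38741	.	SSTR6	SSTR	SSTR6
fruitfly	3L	18550000	18550001	.	Drostar1	SSTR	Drostar1
fruitfly	3L	18480000	18480001	.	Drostar2	SSTR	Drostar2
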