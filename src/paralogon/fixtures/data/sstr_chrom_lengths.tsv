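# Chromosome length sidecar for the SSTR locus fixture.
# Lengths marked here are the published approximate assembly lengths where
# the survey prints one (chicken chromosomes 14/18, stickleback linkage
# groups V/IX/XI); scaffold rows are synthetic placeholders (locus end plus
# a margin) marked placed=false. Chromosomes absent from this sidecar get a
# default generous length and placed=true at load time.
species	chromosome	length	placed
chicken	14	15800000	true
chicken	18	10900000	true
stickleback	groupV	12250000	true
stickleback	groupIX	20240000	true
stickleback	groupXI	16200000	true
anole	GL343263.1	1860000	false
frog	GL172781.1	1170000	false
frog	GL172812.1	1890000	false
frog	GL172724.1	1510000	false
frog	GL172884.1	612431	false
frog	GL172659.1	546171	false
coelacanth	JH126598.1	630000	false
coelacanth	JH126581.1	3570000	false
coelacanth	JH129649.1	310000	false
coelacanth	JH126648.1	2710000	false
coelacanth	JH129247.1	310000	false
coelacanth	JH127490.1	360000	false
zebrafish	Zv9_NA631	103421	false
stickleback	scaffold_47	536211	false
medaka	scaffold5841	500	false
green_puffer	Un_random	59590001	false
fugu	scaffold_115	511361	false
fugu	scaffold_3	103771	false
fugu	scaffold_359	300561	false
fugu	scaffold_407	133361	false
fugu	scaffold_189	367651	false
fugu	scaffold_164	138741	false
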