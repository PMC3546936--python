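mirna	sequence	read_count	locus
ipu-miR-24b	uggcucaguucagcaggaac	748	2∶33623651.33623708:+
ipu-miR-7547	agcggcgucagaagcgauggcc	82	7∶33269277.33269339:+
ipu-miR-101a-3p	caucagcacugugauaacuga	30	6∶31057627.31057683:-
ipu-miR-7147	uguaccaugcugguagccagu	53	24∶10720304.10720362:-
ipu-miR-29a	acugauuuccucugguguu	215	23∶20637186.20637247:-
ipu-miR-16c	ccagcagcacggucaauacug	52	1∶47219524.47219591:+
ipu-miR-199b	uaaccaaugugcagacuacugu	39	5∶1695989.1696054:+
ipu-miR-7548	agccgcggcuguaggagc	192	23∶30968675.30968755:+
ipu-miR-203c	uugaacuguuaagaaccacugc	327	17∶45975697.45975757:-
ipu-miR-551	gcgacccauccuugguuucu	10	15∶34583545.34583600:+
ipu-miR-7549	gaucggugcagcggcggc	291	16∶1499061.1499105:-
ipu-miR-129b	uuugggguaagggcuuccuggcu	4	4∶18115667.18115726:+
ipu-miR-7550	auccggcucgaaggacca	844	13∶37954231.37954286:-
ipu-miR-3618	gauuuccaauaauugagacagu	372	5∶26190297.26190355:+
ipu-miR-7551	ggggccugaguccuucugg	88	6∶52967777.52967859:+
ipu-miR-7552	aaugucccuuaauuguuugguu	85	12∶13216988.13217053:-
ipu-miR-7553	ugacgucauuagcgacccgacc	364	7∶33269276.33269336:-
ipu-miR-7554	acauuuugucuaucugaaa	2	7∶1429428.1429502:-
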