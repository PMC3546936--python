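mirna	sequence	read_count	locus
ipu-miR-7555	cuccagcccggacacccaggac	54	gi|204069919|gb|FD326800.1|FD326800∶128.187:-
ipu-miR-7556	uacaguaacuugaagacaacgu	38	gi|204084719|gb|FD331302.1|FD331302∶133.194:+
ipu-miR-7557	ugcuugcguucugucuguucccu	27	gi|224241675|gb|GH686669.1|GH686669∶235.295:+
ipu-miR-7558a	ggcugagauugggagcacucccu	14	gi|18646130|gb|BM494949.1|BM494949∶104.155:+
ipu-miR-7559	ugccacacgacugcucagcuca	61	gi|224281223|gb|GH675949.1|GH675949∶558.611:+
ipu-miR-7560	uaccugucugcaaucuugaagc	10	gi|224250215|gb|GH657351.1|GH657351∶527.586:+
ipu-miR-7558b	agcugagauugggagcacacuc	29	gi|224238044|gb|GH682245.1|GH682245∶458.509:-
ipu-miR-7561	ugauucagagucgagcucgcuu	49	gi|204112847|gb|FD367553.1|FD367553∶710.773:+
ipu-miR-7562	cacacacacucaugaacacaca	10	gi|224239931|gb|GH646923.1|GH646923∶14.75:-
ipu-miR-7563a	aaccgcguacuugccuacuaua	7	gi|201030860|gb|FD036996.1|FD036996∶371.455:-
ipu-miR-7563b	accgcguacuuaccuacuguaug	22	gi|204062776|gb|FD116111.1|FD116111∶156.232:-
ipu-miR-7564	uuucagagccagagaucgacagc	6	gi|204284216|gb|FD314225.1|FD314225∶213.281:-
ipu-miR-7563c	accgcguacuuaccuacuguau	26	gi|40575287|gb|CK414333.1|CK414333∶481.563:+
ipu-miR-7565	uuccugcugaacugagccagu	20	gi|204269725|gb|FD364850.1|FD364850∶619.675:+
ipu-miR-7566	ucaucggcucaucagacacgc	29	gi|40573358|gb|CK412696.1|CK412696∶750.807:+
ipu-miR-7567	uugcccagaucgaucgccagcu	5	gi|56167725|gb|CV991851.1|CV991851∶94.162:+
ipu-miR-7568	cugaccgaccaagugcugaau	4	gi|204080548|gb|FD371264.1|FD371264∶583.636:-
ipu-miR-7569	uauaaucuugauguuucucca	26	gi|40572877|gb|CK412282.1|CK412282∶114.188:+
ipu-miR-7570	uucuuaugugcgccggcacucu	2	gi|118496311|gb|EE993615.2|EE993615∶401.459:+
ipu-miR-7571	caggcuacaugacaccacccuga	30	gi|18393650|gb|BM425126.1|BM425126∶50.110:+
ipu-miR-7572	gauugcagcuuuacaguguuucc	3	gi|200944081|gb|FD030799.1|FD030799∶333.394:-
ipu-miR-7573	aggcugagccugauggcacugag	2	gi|204132990|gb|FD262187.1|FD262187∶225.297:+
ipu-miR-7574	uuuaucucuacucgcucgucu	9	gi|204025299|gb|FD323591.1|FD323591∶204.260:-
ipu-miR-7575	gcauggucaugaucaugguc	2	gi|30224238|gb|CB938847.1|CB938847∶656.706:+
ipu-miR-7576	agaacauucaaccgccgcaca	2	gi|204187343|gb|FD336486.1|FD336486∶198.251:+
ipu-miR-7577	cucggacauuuuggacucgga	14	gi|204280683|gb|FD352971.1|FD352971∶10.55:-
ipu-miR-457b	uagcagcacaucaauauuggca	2288	gi|281572797|gb|FI880023.1|FI880023∶146.211:-
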