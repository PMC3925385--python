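otu_id	phylum	class	order	family	genus	species	identity_pct	accession	level	clade_rank	s1	s2	s3	s4	s5	s6	s7	s8	s9	s10	s11	s12	s13	s14	s15	s16	s17	s18	s19	s20	s21	s22	s23	s24	s25	s26	s27	s28	s29	s30
Metaphire hilgendorfi	Annelida	Oligochaeta	Haplotaxida	Megascolecidae	Metaphire	Metaphire hilgendorfi	99	AB542630.1	species	species	0	0	0	0	0	0	0	0	0	0	0	0	0	3	0	0	0	3	0	0	0	0	0	0	0	0	0	0	0	0
Asellus sp. 1	Arthropoda	Malacostraca	Isopoda	Asellidae	Asellus		89	AY531829.1	genus	genus	0	0	0	0	0	0	0	0	0	0	0	1	1	0	0	0	1	0	1	3	10	2	0	0	0	0	0	0	9	0
Asellus sp. 2	Arthropoda	Malacostraca	Isopoda	Asellidae	Asellus		83	DQ144785.1	genus	genus	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	1	0
Macrobrachium nipponense	Arthropoda	Malacostraca	Decapoda	Palaemonidae	Macrobrachium	Macrobrachium nipponense	100	JN874519.1	species	species	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	2	0	0	0	0	0	7	0	0	0	0	0
Daphnia sp.	Arthropoda	Branchiopoda	Diplostraca	Daphniidae	Daphnia		98	EF375867.1	genus	genus	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Cyclops sp. 1	Arthropoda	Maxillopoda	Cyclopoida	Cyclopidae	Cyclops		97	KC627290	genus	genus	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Cyclops sp. 2	Arthropoda	Maxillopoda	Cyclopoida	Cyclopidae	Cyclops		96	KC627290	genus	genus	0	0	0	0	0	0	0	0	0	0	4	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Paracercion calamorum	Arthropoda	Insecta	Odonata	Coenagrionidae	Paracercion	Paracercion calamorum	100	AB708522.1	species	species	0	0	0	0	0	0	0	8	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Paracercion hieroglyphicum	Arthropoda	Insecta	Odonata	Coenagrionidae	Paracercion	Paracercion hieroglyphicum	99	AB708524.1	species	species	0	0	0	0	0	0	0	2	3	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Paracercion sp.	Arthropoda	Insecta	Odonata	Coenagrionidae	Paracercion		96	AB708534.1	genus	genus	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Chironomus kiiensis	Arthropoda	Insecta	Diptera	Chironomidae	Chironomus	Chironomus kiiensis	99	KC407765.1	species	species	6	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Chironomus nipponensis	Arthropoda	Insecta	Diptera	Chironomidae	Chironomus	Chironomus nipponensis	99	JN887051.1	species	species	0	0	0	0	0	0	3	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Chironomus plumosus	Arthropoda	Insecta	Diptera	Chironomidae	Chironomus	Chironomus plumosus	99	KC407771.1	species	species	0	0	0	2	0	0	0	0	0	0	0	3	0	0	1	0	0	0	0	1	0	0	1	0	0	0	0	0	0	0
Glyptotendipes tokunagai	Arthropoda	Insecta	Diptera	Chironomidae	Glyptotendipes	Glyptotendipes tokunagai	99	JQ350718.1	species	species	0	0	0	8	0	0	0	0	0	0	0	1	5	0	0	1	8	0	1	1	0	0	0	6	0	0	0	0	0	0
Dicrotendipes nervosus	Arthropoda	Insecta	Diptera	Chironomidae	Dicrotendipes	Dicrotendipes nervosus	99	JF412128.1	species	species	2	1	0	0	0	0	0	0	0	0	0	0	0	0	0	4	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Polypedilum cultellatum	Arthropoda	Insecta	Diptera	Chironomidae	Polypedilum	Polypedilum cultellatum	99	JF412156.1	species	species	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
Chironomus sp.1	Arthropoda	Insecta	Diptera	Chironomidae	Chironomus		96	JF412075.1	genus	genus	2	9	6	0	10	10	7	0	0	0	2	0	0	0	0	1	0	1	0	0	0	0	0	0	0	0	0	0	0	0
Chironomus sp.2	Arthropoda	Insecta	Diptera	Chironomidae	Chironomus		99	JF412065.1	genus	genus	0	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Chironomidae	Arthropoda	Insecta	Diptera	Chironomidae			90	AY752674.1	family	family	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Caenidae	Arthropoda	Insecta	Ephemeroptera	Caenidae			82	JQ662051.1	family	family	0	0	0	0	0	0	0	0	3	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Hydra oligactis	Cnidaria	Hydrozoa	Anthomedusae	Hydridae	Hydra	Hydra oligactis	99	GU722868.1	species	species	0	0	0	0	0	0	0	0	0	0	0	0	0	6	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Hemibarbus labeo	Chordata	Actinopterygii	Cypriniformes	Cyprinidae	Hemibarbus	Hemibarbus labeo	99	HQ536371.1	species	species	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	1	0	0	0	5	0	0	0	0	2	0	0	0	0	10
Opsariichthys uncirostris amurensis	Chordata	Actinopterygii	Cypriniformes	Cyprinidae	Opsariichthys	Opsariichthys uncirostris amurensis	99	HQ536421.1	species	species	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Cyprinidae	Chordata	Actinopterygii	Cypriniformes	Cyprinidae			98	HQ536348.1	family	family	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Tachysurus fulvidraco	Chordata	Actinopterygii	Siluriformes	Bagridae	Tachysurus	Tachysurus fulvidraco	99	HM641815.1	species	species	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	7	0	0	0	0	0	1	0	0	10	0	0
Micropterus salmoides	Chordata	Actinopterygii	Perciformes	Centrarchidae	Micropterus	Micropterus salmoides	100	DQ536425.1	species	species	0	0	0	0	0	0	0	0	0	0	0	4	5	0	9	0	0	7	0	0	0	9	8	4	0	0	0	0	0	0
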