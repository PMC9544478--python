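chr	Coordinates	Context	ID	Description	Zygosity
1	21761950–55	Exon	AT1G58602	LRR and NB-ARC domains-containing disease resistance protein	(−/−)
2	149387–91	Exon	AT2G01290	Cytosolic ribose-5-phosphate isomerase	(−/−)
3	19300993–97	Exon	AT3G52020	Serine carboxypeptidase-like 39	(+/−)
3	22631755–59	Exon	AT3G61150	Homeodomain GLABROUS 1; HD-ZIP IV family	(+/−)
5	853776–80	Exon	AT5G03435	Ca2+-dependent plant phosphoribosyltransferase family protein	(−/−)
5	10632816–20	TE	AT5G28626	AT5TE38720; SADHU; Sadhu noncoding retroTE family	(−/−)
5	18850327–31	Promoter	AT5G46490	Disease resistance protein (TIR-NBS-LRR class) family	(−/−)
5	21050239–43	Intron	AT5G51800	Protein kinase superfamily protein	(−/−)
5	21602030–34	Exon	AT5G53240	Hypothetical protein (DUF295)	(+/−)
5	22846432–36	Intron	AT5G56400	FBD, F-box, Skp2-like and Leucine Rich Repeat domains-containing protein	(+/−)
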