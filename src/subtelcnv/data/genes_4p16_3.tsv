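start	end	cytoband	symbol	description	model_evidence
609373	654571	4p16.3	PDE6B	Phosphodiesterase 6B, cGMP-specific, rod, beta (congenital stationary night blindness 3, autosomal dominant)	Best RefSeq
656225	658122	4p16.3	ATP5I	ATP synthase, H+ transporting, mitochondrial F0 complex, subunit E	Best RefSeq
661711	665817	4p16.3	MYL5	Myosin, light chain 5, regulatory	Best RefSeq
665618	672973	4p16.3	MFSD7	Major facilitator superfamily domain containing 7	mRNA
689573	754428	4p16.3	PCGF3	Polycomb group ring finger 3	Best RefSeq
719829	721544	4p16.3	LOC100128084	Hypothetical protein LOC100128084	mRNA
764588	765632	4p16.3	LOC100129917	Hypothetical protein LOC100129917	mRNA
768745	809945	4p16.3	CPLX1	Complexin 1	mRNA
833065	916174	4p16.3	GAK	Cyclin G associated kinase	mRNA
916262	942444	4p16.3	TMEM175	Transmembrane protein 175	Best RefSeq
942675	957344	4p16.3	DGKQ	Diacylglycerol kinase, theta 110 kDa	Best RefSeq
962861	977224	4p16.3	SLC26A1	Solute carrier family 26 (sulfate transporter), member 1	Best RefSeq
970785	988317	4p16.3	IDUA	Iduronidase, alpha-L-	mRNA
995610	1010686	4p16.3	FGFRL1	Fibroblast growth factor receptor-like 1	Best RefSeq
1044654	1045386	4p16.3	LOC100132787	Hypothetical protein LOC100132787	mRNA
1055269	1097350	4p16.3	RNF212	Ring finger protein 212	Best RefSeq
1116050	1129814	4p16.3	LOC100133135	Hypothetical protein LOC100133135	Protein
1135541	1135957	4p16.3	FLJ35816	FLJ35816 protein	Protein
1149293	1149712	4p16.3	LOC100131106	Hypothetical protein LOC100131106	Protein
1150723	1156597	4p16.3	SPON2	Spondin 2, extracellular matrix protein	Best RefSeq
1184431	1185198	4p16.3	LOC100130872	Hypothetical protein LOC100130872	mRNA
1195228	1232908	4p16.3	CTBP1	C-terminal binding protein 1	Best RefSeq
1234177	1236616	4p16.3	C4orf42	Chromosome 4 open reading frame 42	Best RefSeq
1273672	1323925	4p16.3	MAEA	Macrophage erythroblast attacher	Best RefSeq
1331104	1371732	4p16.3	KIAA1530	KIAA1530	mRNA
1375340	1379782	4p16.3	CRIPAK	Cysteine-rich PAK1 inhibitor	mRNA
1380072	1392453	4p16.3	NKX1-1	NK1 homeobox 1	Protein
1484196	1519086	4p16.3	LOC100133199	Similar to RE32881p	mRNA
1611605	1655516	4p16.3	FAM53A	Family with sequence similarity 53, member A	Best RefSeq
1664325	1683828	4p16.3	SLBP	Stem-loop (histone) binding protein	Best RefSeq
1687477	1692882	4p16.3	TMEM129	Transmembrane protein 129	Best RefSeq
1693062	1716696	4p16.3	TACC3	Transforming, acidic coiled-coil containing protein 3	Best RefSeq
1765421	1780396	4p16.3	FGFR3	Fibroblast growth factor receptor 3 (achondroplasia, thanatophoric dwarfism)	Best RefSeq
1784558	1827772	4p16.3	LETM1	Leucine zipper-EF-hand containing transmembrane protein 1	Best RefSeq
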