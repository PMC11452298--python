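position	variant_id	hgvs	ref	alt	gene	splice_site	splicing_event	spliceai_gain	ptc	clinvar	af	n_hetero	n_homo
chr1:9,304,978	rs139855605	ENST00000377403.2:c.1-15_1-8del	CCCCAGGCA	C	H6PD	A	S	0.96	Not in CDS	-	0.1199	45	7
chr2:135,626,611	rs201426305	ENST00000392929.2:r.109-1del	GC	G	CCNT2-AS1	A	S	0.20	Not in CDS	-	0.0139	3	0
chr5:64,103,424	rs551560409	ENST00000508024.1:c.939-2_939-1insGC	A	AGC	CWC27	A	E	0.52	PTC	-	0.0072	2	0
chr8:42,952,662	rs149140769	ENST00000331373.5:c.1-6029_1-6026del	TAAAG	T	POMK	A	S	0.71	Not in CDS	Benign	0.0152	4	0
chr8:91,057,230	rs147668665	ENST00000220764.2:c.885+8del	GT	G	DECR1	D	E	0.00	PTC	Benign	0.0131	6	0
chr12:7,086,294	ss1388028816	ENST00000261407.4:c.1461+16del	AC	A	LPCAT3	D	S	0.98	Not in CDS	-	0.0182	13	0
chr13:45,957,308	rs35686266	ENST00000517509.1:r.927del	AG	A	TPT1-AS1	D	S	0.23	Not in CDS	-	0.0791	34	2
chr14:101,540,816	rs11310304	ENST00000448840.2:r.354+1del	AC	A	ENSG00000230805	D	S	0.20	Not in CDS	-	0.0223	11	0
chr15:65,108,135	rs536092356	ENST00000333425.6:c.1878del	TC	T	PIF1	A	S	0.00	PTC	-	0.0101	4	0
chr16:1,822,797	rs4027362	ENST00000397375.2:c.321+2_321+3insACCT	C	CACCT	MRPS34	D	E	0.83	PTC	Benign	0.4925	119	54
chr16:88,926,388	rs543819824	ENST00000301021.3:c.374+8_374+9insTACTTTCTGTGTCTGCATCCAGTCCAGGTGGGCCT	C	CTACTTTCTGTGTCTGCATCCAGTCCAGGTGGGCCT	TRAPPC2L	D	E	0.71	PTC	-	0.0565	13	5
chr17:15,343,524	rs71150251	ENST00000522212.2:c.492+45_492+46insCTT	C	CCTT	TVP23C-CDRT4	D	E	0.83	Not in CDS	-	0.9725	6	229
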