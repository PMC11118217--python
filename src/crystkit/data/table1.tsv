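organism	protein	uniprot_id	method	length	cys_count	cys_pct	met_count	met_pct	block
Branchiostoma floridae	S-crystallin	C3YKG6_BRAFL	1	128	6	4.7	4	3.1	betagamma
Ciona intestinalis	Betagamma-crystallin	F6Q2R9_CIOIN	3	84	0	0.0	0	0.0	betagamma
Eptatretus burgeri	Betagamma-crystallin	A0A8C4N311_EPTBU	3	153	7	4.6	3	2.0	betagamma
Petromyzon marinus	gammaS-crystallin	S4REP0_PETMA	3	176	9	5.1	8	4.5	betagamma
Danio rerio	gammaS1-crystallin	E9QE97_DANRE	1	178	8	4.5	2	1.1	gammaS
Danio rerio	gammaS2-crystallin	Q5XTP1_DANRE	1	174	8	4.6	2	1.1	gammaS
Latimeria chalumnae	gammaS-crystallin	H2ZWR5_LATCH	3	178	7	3.9	6	3.4	gammaS
Ornithorhynchus anatinus	gammaS-crystallin	F6SLN9_ORNAN	1	178	6	3.4	3	1.7	gammaS
Macropus fuliginosus	gammaS-crystallin	CRYGS_MACFL	4	178	8	4.5	4	2.2	gammaS
Mus musculus	gammaS-crystallin	CRYGS_MOUSE	1	178	7	3.9	4	2.2	gammaS
Bos taurus	gammaS-crystallin	CRYGS_BOVIN	1	178	6	3.4	6	3.4	gammaS
Homo sapiens	gammaS-crystallin	CRYGS_HUMAN	1	178	7	3.9	5	2.8	gammaS
Anolis carolinensis	gammaS-crystallin	A0A803TS30_ANOCA	1	179	5	2.8	5	2.8	gammaS
Alligator mississippiensis	gammaS-crystallin	A0A151NH35_ALLMI	2	182	7	3.8	4	2.2	gammaS
Gallus gallus	gammaS-crystallin	A0A8V0ZYD9_CHICK	1	175	7	4.0	3	1.7	gammaS
Macropus fuliginosus	gammaD-crystallin	CRGD_MACFL	4	174	8	4.6	8	4.6	gammaD_like
Mus musculus	gammaD-crystallin	CRGD_MOUSE	1	174	7	4.0	7	4.0	gammaD_like
Bos taurus	gammaD-crystallin	CRGD_BOVIN	4	174	5	2.9	5	2.9	gammaD_like
Homo sapiens	gammaD-crystallin	CRGD_HUMAN	1	174	6	3.4	5	2.9	gammaD_like
Alligator mississippiensis	gammaD-crystallin	A0A151N9E2_ALLMI	2	175	6	3.4	7	4.0	gammaD_like
Xenopus laevis	gamma-crystallin 1	CRG1_XENLA	2	175	5	2.9	5	2.9	gammaD_like
Xenopus laevis	gamma-crystallin 2	CRG2_XENLA	4	175	7	4.0	6	3.4	gammaD_like
Xenopus laevis	gamma-crystallin 3	CRG3_XENLA	2	175	6	3.4	5	2.9	gammaD_like
Xenopus laevis	gamma-crystallin 4	A0A8J0U6M7_XENLA	1	175	7	4.0	6	3.4	gammaD_like
Xenopus laevis	gamma-crystallin 5	A0A8J0U8K1_XENLA	1	175	6	3.4	5	2.9	gammaD_like
Chiloscyllium indicum	gammaS1-crystallin	CRGS1_CHIID	4	173	7	4.0	10	5.8	gammaD_like
Chiloscyllium indicum	gammaS2-crystallin	CRGS2_CHIID	2	173	6	3.5	9	5.2	gammaD_like
Chiloscyllium indicum	gammaM2-crystallin	CRGM2_CHIID	4	176	8	4.5	9	5.1	gammaD_like
Latimeria chalumnae	gammaM2-crystallin	H3B445_LATCH	3	176	9	5.1	4	2.3	gammaD_like
Danio rerio	gammaS3-crystallin	Q5XTN7_DANRE	1	183	6	3.3	7	3.8	gammaD_like
Danio rerio	gammaS4-crystallin	Q5XTN2_DANRE	1	176	7	4.0	2	1.1	gammaD_like
Chiloscyllium indicum	gammaM1-crystallin	CRGM1_CHIID	4	120	10	8.3	27	22.5	gammaM
Danio rerio	gammaM1-crystallin	Q5XTN6_DANRE	1	178	8	4.5	19	10.7	gammaM
Danio rerio	gammaM2-crystallin	A0A8N7TEM3_DANRE	1	174	10	5.7	22	12.6	gammaM
Danio rerio	gammaM2a-crystallin	Q4ZHG3_DANRE	1	181	10	5.5	24	13.3	gammaM
Danio rerio	gammaM2c-crystallin	Q5XTP2_DANRE	1	175	10	5.7	22	12.6	gammaM
Danio rerio	gammaM2d1-crystallin	B0S6M3_DANRE	2	175	10	5.7	23	13.1	gammaM
Danio rerio	gammaM3-crystallin	Q5XTM9_DANRE	1	174	10	5.7	13	7.5	gammaM
Danio rerio	gammaM4-crystallin	Q5XTN5_DANRE	1	174	9	5.2	10	5.7	gammaM
Danio rerio	gammaM5-crystallin	Q5XJ63_DANRE	1	177	11	6.2	12	6.8	gammaM
Danio rerio	gammaM6-crystallin	Q5XTN4_DANRE	2	177	7	4.0	11	6.2	gammaM
Danio rerio	gammaM7-crystallin	Q5XTN3_DANRE	1	174	8	4.6	16	9.2	gammaM
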