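protein_id	name	tffd_start	tffd_end	tmd_index	tmd_start	tmd_end	tmd_score	topology	nls	localizations	ptm_kind	ptm_position	helix_motif	kr_tmd	kr_flank	n_alt_transcripts
AIL6	AIL6	389	440	1	301	321	0.702	I		mt;nuc	ph(4)			0	K(3) R(1)	2
ANAC028	ANAC028	6	143	1	609	630	0.570			nuc	nt(1)*			K(2)	K(5) R(1)
AT2G13960	AT2G13960	40	86	1	9	29	0.582	II		sec;nuc;pm			[GxxN]	0	K(4)*
AT2G29660	AT2G29660	126	149	1	9	29	0.477	I		sec;mt;nuc	ph(1)*			R(1)	K(6) R(4)*
AT3G04930	AT3G04930	137	235	1	372	395	0.486	II		nuc;pm	ph(5)*			0	K(1)	1
AT5G25475	AT5G25475	78	155	1	52	75	0.606	I		mt			[PxxN]	K(1)	K(1) R(5)*	2
AT5G63280	AT5G63280	105	128	1	223	246	0.836	II		sec;nuc	nt(1);ng(1)*;ac(1);ro(1)			0	K(4) R(1)*
bHLH035	bHLH035	58	101	1	203	224	0.581	II		nuc	ph(1)*			0	K(2)	3
bHLH035	bHLH035	58	101	2	190	213	0.360	II		nuc	ph(1)*			K(1)	K(2) R(1)	3
bHLH035	bHLH035	58	101	3	214	245	0.871	I		nuc	ph(1)*		[PN]	R(1)		3
bHLH115	bHLH115	136	182	1	190	211	0.363			nuc				K(5)	K(1) R(2)
bHLH131	bHLH131	1351	1397	1	1242	1262	0.463			nuc;sec;pl;mt	ph(1)			0	K(2)	2
bHLH131	bHLH131	1351	1397	2	1277	1297	0.341			nuc;sec;pl;mt	ph(1)			0		2
bZIP7	bZIP7	197	254	1	38	59	0.662			nuc	ph(3)*;ng(1)			K(1)	0	3
bZIP17	bZIP17	226	287	1	364	387	0.798	I		nuc;er;pm	ph(1)		[GA]	K(1)	K(7)*
bZIP28	bZIP28	192	237	1	321	344	0.848	I		nuc;sec;er;pm				K(1)	K(7) R(1)*
bZIP49	bZIP49	172	219	1	286	309	0.755	I		nuc			[GA]	K(1)	K(6) R(1)*
bZIP60	bZIP60	141	183	1	217	240	0.693	II		nuc				0	K(2) R(1)
CAMTA1	CAMTA1	81	188	1	192	211	0.380	I		nuc	ph(10)*;na(1);nt(1)			R(1)	K(1) R(3)
CAMTA5	CAMTA5	30	146	1	579	600	0.683			nuc;golgi;pm	ph(3)*;sm(1)			0	K(4)	1
FRF3	FRF3	25	110	1	115	136	0.424			mt;cyt				R(1)	K(2) R(1)	1
GPL2	GPL2	61	155	1	328	348	0.786			nuc	ph(4)*		[PxxP]	0	0
HHO5	HHO5	218	272	1	64	85	0.567			nuc	ph(1)			R(1)	K(3) R(1)	3
LD	LD	66	122	1	222	243	0.496			nuc	ph(2)*;ub(1)			K(1)	K(2) R(1)
LHL2	LHL2	529	566	1	123	144	0.537			nuc				0	K(1) R(4)	2
LOL1	LOL1	70	171	1	24	47	0.488	II		sec;nuc				0	K(3) R(1)
MAMYB	MAMYB	159	193	1	35	55	0.770	I		nuc;er;golgi;pm	ph(14)*;na(1)			0	K(1)
MAMYB	MAMYB	159	193	2	61	84	0.575	II		nuc;er;golgi;pm	ph(14)*;na(1)		[PxxP]	K(1)
NFXL2	NFXL2	247	452	1	840	863	0.462	II		nuc	ph(1)*			K(1)	K(2) R(2)
NGAL2	NGAL2	29	142	1	198	221	0.469	II		nuc				0	K(2)	2
NLP3	NLP3	495	546	1	41	64	0.550	I		mt;nuc				0	0
NOK	NOK	57	155	1	30	51	0.345			nuc	nt(1)			K(1) R(1)	K(1) R(1)
NTL1	NTL1	10	135	1	497	520	0.792	I		nuc;er;pm			[GA]	0	K(7) R(1)*
NTL2	NTL2	24	151	1	605	625	0.760	II		nuc;er;pm				0	K(5) R(1)*
NTL3	NTL3	17	143	1	535	555	0.718	II		nuc;er;pm			[GA]	K(1)	K(2) R(2)
NTL4	NTL4	9	136	1	522	545	0.714	II		nuc;pm;er				K(1)	K(1)
NTL5	NTL5	15	140	1	316	334	0.528	II		nuc;er;pm				R(1)	K(1) R(1)
NTL6	NTL6	13	141	1	442	462	0.523	II		nuc;er;pm	ph(9)*			R(1)	K(3) R(1)
NTL7	NTL7	17	143	1	525	548	0.856	II		nuc;cyt;er;pm	ph(1)*		[GA]	R(1)	K(3) R(2)
NTL8	NTL8	14	140	1	312	332	0.759	II		nuc;pm;er				0	K(4) R(2)
NTL9	NTL9	9	135	1	488	511	0.528	II		nuc;golgi;er;pm				K(1) R(1)	K(2) R(5)*
NTL10	NTL10	5	138	1	410	428	0.773	II		nuc;er;pm	ph(3)*			0	K(2)
NTL11	NTL11	9	136	1	541	564	0.571	II		nuc;er;pm	ph(2)*			K(1) R(1)	K(1)
NTL13	NTL13	22	147	1	319	339	0.480	II		nuc;er;pm				0	K(2) R(1)
NTM1	NTM1	6	136	1	445	468	0.432	II		nuc;er;pm	ph(4)*			K(2) R(2)	K(4) R(2)
OBP3	OBP3	118	177	1	42	62	0.595			mt;nuc	ph(2)*			0	0	5
RLT2	RLT2	18	74	1	518	539	0.554			nuc;golgi	ph(24)*;ac(1)*			R(1)	K(4)	3
SCP	SCP	36	136	1	14	37	0.550	II		sec;nuc			[GA]	R(1) K(1)	K(1) R(3)
SPL1	SPL1	105	182	1	835	858	0.641	II		nuc;er;pm	ph(3)*			R(1)	K(2) R(2)
SPL7	SPL7	137	213	1	762	782	0.627	II		nuc	ph(1)*			0	K(2) R(3)
SPL12	SPL12	126	203	1	881	904	0.641	I		nuc;er;pm	ph(10)*			R(1)	K(3) R(1)
SPL14	SPL14	119	196	1	995	1018	0.614	II		nuc;er;pm	ph(3)*			0	K(1) R(3)
SPL16	SPL16	82	158	1	978	1001	0.614	II		nuc;pm				0	K(2) R(3)
SRS8	SRS8	46	140	1	144	164	0.375	II		nuc	ph(1)			0	K(1) R(1)	3
WIP4	WIP4	256	362	1	42	63	0.468			nuc;sec				0	K(1) R(1)
ZFN2	ZFN2	45	334	1	444	465	0.720			nuc	ph(8)*;na(1);nt(1);my(1);ub(1)			K(1)	0	2
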