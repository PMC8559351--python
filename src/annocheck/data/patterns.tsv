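# Built-in motif pattern set, v1. One pattern per line: ID<TAB>NAME<TAB>PATTERN
# EF_HAND / KINASE_ATP / KINASE_ST_ACTIVE / MYRISTOYL follow the standard
# PROSITE entries (PS00018 / PS00107 / PS00108 / PS00008). GLOBIN_PROXHIS is a
# simplified proximal-histidine consensus; CECROPIN_LIKE is an approximate
# tryptophan-anchored cecropin consensus. Override with your own file if a
# different operationalization is needed.
EF_HAND	EF-hand calcium-binding loop	D-x-[DNS]-{ILVFYW}-[DENSTG]-[DNQGHRK]-{GP}-[LIVMC]-[DENQSTAGC]-x(2)-[DE]-[LIVMFYW]
KINASE_ATP	Protein kinase ATP-binding region signature	[LIV]-G-{P}-G-{P}-[FYWMGSTNH]-[SGA]-{PW}-[LIVCAT]-{PD}-x-[GSTACLIVMFY]-x(5,18)-[LIVMFYWCSTAR]-[AIVP]-[LIVMFAGCKR]-K
KINASE_ST_ACTIVE	Serine/threonine kinase active-site signature	[LIVMFYC]-x-[HY]-x-D-[LIVMFY]-K-x(2)-N-[LIVMFYCT](3)
WRKY_CORE	WRKY domain core heptapeptide	W-R-K-Y-G-[QK]-K
MYRISTOYL	N-myristoylation site (N-terminal)	<G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}
CECROPIN_LIKE	Cecropin family signature (approximate)	W-[NKR]-[LIVFY]-x-[KRH]-[LIVFYA]-[EAGQKR]-[KRE]-x-[LIVMGER]
GLOBIN_PROXHIS	Globin proximal-histidine region (simplified)	F-x-[LIVMFY]-x(2)-H-x(2)-[KR]
TERPENE_DDXXD	Terpene synthase DDxxD/E metal-binding motif	D-D-x-x-[DE]
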