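gene	transcript	match_kind	position	end_position	exon	allowed_alts	event_class	label
ALK	NM_004304.4	exact_aa	1174	.	.	L	substitution	F1174L
ALK	NM_004304.4	exact_aa	1275	.	.	Q	substitution	R1275Q
BRAF	NM_004333.5	exact_aa	469	.	.	A,E,R,V	substitution	G469A/E/R/V
BRAF	NM_004333.5	exact_aa	594	.	.	G,M	substitution	D594G/M
BRAF	NM_004333.5	aa_region	599	601	.	.	inframe_indel	T599-K601 if-del/ins
BRAF	NM_004333.5	exact_aa	600	.	.	E,K,M,R	substitution	V600E/K/M/R
BRAF	NM_004333.5	exact_aa	601	.	.	E	substitution	K601E
BRCA1	NM_007294.3	any_clear_lof	.	.	.	.	clear_lof	all clear LoF variants (nonsense, frameshift, splice site)
BRCA2	NM_000059.3	any_clear_lof	.	.	.	.	clear_lof	all clear LoF variants (nonsense, frameshift, splice site)
EGFR	NM_005228.4	exact_aa	719	.	.	A,C,S	substitution	G719A/C/S
EGFR	NM_005228.4	exon_event	.	.	19	.	inframe_indel	ex19if-del/ins
EGFR	NM_005228.4	exon_event	.	.	20	.	inframe_ins	ex20 if-ins
EGFR	NM_005228.4	exact_aa	790	.	.	M	substitution	T790M
EGFR	NM_005228.4	exact_aa	797	.	.	S	substitution	C797S
EGFR	NM_005228.4	exact_aa	858	.	.	R	substitution	L858R
EGFR	NM_005228.4	exact_aa	861	.	.	Q	substitution	L861Q
ESR1	NM_000125.3	exact_aa	303	.	.	R	substitution	K303R
ESR1	NM_000125.3	exact_aa	380	.	.	Q	substitution	E380Q
ESR1	NM_000125.3	exact_aa	392	.	.	I	substitution	V392I
ESR1	NM_000125.3	exact_aa	463	.	.	P	substitution	S463P
ESR1	NM_000125.3	exact_aa	533	.	.	M	substitution	V533M
ESR1	NM_000125.3	exact_aa	534	.	.	E	substitution	V534E
ESR1	NM_000125.3	exact_aa	535	.	.	H	substitution	P535H
ESR1	NM_000125.3	exact_aa	536	.	.	H,P,Q,R	substitution	L536H/P/Q/R
ESR1	NM_000125.3	exact_aa	537	.	.	C,N,S	substitution	Y537C/N/S
ESR1	NM_000125.3	exact_aa	538	.	.	G	substitution	D538G
GNAS	NM_000516.5	exact_aa	201	.	.	C,H	substitution	R201C/H
H3F3A	NM_002107.4	exact_aa	28	.	.	M	substitution	K28M
H3F3A	NM_002107.4	exact_aa	35	.	.	R,W	substitution	G35R/W
HRAS	NM_005343.3	exact_aa	12	.	.	C,D,S,V	substitution	G12C/D/S/V
HRAS	NM_005343.3	exact_aa	13	.	.	C,D,R,S,V	substitution	G13C/D/R/S/V
HRAS	NM_005343.3	exact_aa	61	.	.	H,K,L,R	substitution	Q61H/K/L/R
IDH1	NM_005896.3	exact_aa	132	.	.	C,G,H,L,S	substitution	R132C/G/H/L/S
IDH2	NM_002168.3	exact_aa	140	.	.	L,Q,W	substitution	R140L/Q/W
IDH2	NM_002168.3	exact_aa	172	.	.	K,M,S	substitution	R172K/M/S
KIT	NM_000222.2	aa_region	419	419	8	.	inframe_del	D419 if-del
KIT	NM_000222.2	aa_region	501	504	9	.	inframe_ins	S501-F504 if-ins
KIT	NM_000222.2	aa_region	550	560	11	.	inframe_indel	K550-V560 if-indel
KIT	NM_000222.2	exact_aa	557	.	11	G,R	substitution	W557G/R
KIT	NM_000222.2	exact_aa	559	.	11	A,D	substitution	V559A/D
KIT	NM_000222.2	exact_aa	560	.	11	D	substitution	V560D
KIT	NM_000222.2	exact_aa	576	.	11	P	substitution	L576P
KIT	NM_000222.2	exact_aa	642	.	13	E	substitution	K642E
KIT	NM_000222.2	exact_aa	654	.	13	A	substitution	V654A
KIT	NM_000222.2	exact_aa	670	.	14	I	substitution	T670I
KIT	NM_000222.2	exact_aa	816	.	17	H,V,Y	substitution	D816H/V/Y
KIT	NM_000222.2	exact_aa	822	.	17	K	substitution	N822K
KRAS	NM_004985.4	exact_aa	12	.	.	A,C,D,F,R,S,V	substitution	G12A/C/D/F/R/S/V
KRAS	NM_004985.4	exact_aa	13	.	.	C,D,R,S,V	substitution	G13C/D/R/S/V
KRAS	NM_004985.4	exact_aa	59	.	.	T	substitution	A59T
KRAS	NM_004985.4	exact_aa	61	.	.	H,K,L,R	substitution	Q61H/K/L/R
KRAS	NM_004985.4	exact_aa	117	.	.	N	substitution	K117N
KRAS	NM_004985.4	exact_aa	146	.	.	T	substitution	A146T
MET	NM_001127500.3	splice_event	.	.	14	.	skipping	ex14 skipping
NRAS	NM_002524.4	exact_aa	12	.	.	A,C,D,R,S,V	substitution	G12A/C/D/R/S/V
NRAS	NM_002524.4	exact_aa	13	.	.	C,D,R,S,V	substitution	G13C/D/R/S/V
NRAS	NM_002524.4	exact_aa	59	.	.	T	substitution	A59T
NRAS	NM_002524.4	exact_aa	61	.	.	H,K,L,R	substitution	Q61H/K/L/R
NRAS	NM_002524.4	exact_aa	117	.	.	N	substitution	K117N
NRAS	NM_002524.4	exact_aa	146	.	.	T	substitution	A146T
PDGFRA	NM_006206.5	aa_region	566	577	.	.	inframe_del	S566_E577 if-del
PDGFRA	NM_006206.5	exact_aa	842	.	.	V	substitution	D842V
PDGFRA	NM_006206.5	aa_region	842	843	.	.	inframe_del	D842_I843 if-del
PDGFRA	NM_006206.5	exact_aa	561	.	.	D	substitution	V561D
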