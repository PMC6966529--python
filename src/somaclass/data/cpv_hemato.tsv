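gene	transcript	match_kind	position	end_position	exon	allowed_alts	event_class	label
ASXL1	NM_015338.5	none	.	.	.	.	.	none
CALR	NM_004343.3	exon_event	.	.	9	.	out_of_frame_del	ex9of-del
CALR	NM_004343.3	exon_event	.	.	9	.	out_of_frame_ins	ex9of-ins
CEBPA	NM_004364.3	none	.	.	.	.	.	none
CSF3R	NM_156039.3	exact_aa	618	.	.	I	substitution	T618I
DNMT3A	NM_175629.2	exact_aa	882	.	.	C,H	substitution	R882C/H
EZH2	NM_004456.4	exact_aa	646	.	.	F,H,N,S	substitution	Y646F/H/N/S
FLT3	NM_004119.2	exon_event	.	.	14	.	duplication	ex14if-dup
FLT3	NM_004119.2	exact_aa	835	.	.	A,E,H,V,Y	substitution	D835A/E/H/V/Y
IDH1	NM_005896.3	exact_aa	132	.	.	C,G,H,L,S	substitution	R132C/G/H/L/S
IDH2	NM_002168.3	exact_aa	140	.	.	L,Q,W	substitution	R140L/Q/W
IDH2	NM_002168.3	exact_aa	172	.	.	K,M,S	substitution	R172K/M/S
JAK2	NM_004972.3	exon_event	.	.	12	.	inframe_indel	ex12 if-del/if-dup
JAK2	NM_004972.3	exact_aa	617	.	.	F	substitution	V617F
KIT	NM_000222.2	see_solid	.	.	.	.	.	see CPV Solid list
MPL	NM_005373.2	exact_aa	505	.	.	N	substitution	S505N
MPL	NM_005373.2	exact_aa	515	.	.	.	any_missense	W515any ms
NPM1	NM_002520.6	exon_event	.	.	11	.	out_of_frame_ins	ex11of-ins
RUNX1	NM_001754.4	none	.	.	.	.	.	none
SETBP1	NM_015559.3	exact_aa	868	.	.	N	substitution	D868N
SETBP1	NM_015559.3	exact_aa	870	.	.	S	substitution	G870S
SF3B1	NM_012433.3	exact_aa	622	.	.	D	substitution	E622D
SF3B1	NM_012433.3	exact_aa	625	.	.	C,H	substitution	R625C/H
SF3B1	NM_012433.3	exact_aa	662	.	.	Q	substitution	H662Q
SF3B1	NM_012433.3	exact_aa	666	.	.	N,R,T	substitution	K666N/R/T
SF3B1	NM_012433.3	exact_aa	700	.	.	E	substitution	K700E
SF3B1	NM_012433.3	exact_aa	742	.	.	D	substitution	G742D
SRSF2	NM_003016.4	exact_aa	95	.	.	H,L,R	substitution	P95H/L/R
SRSF2	NM_003016.4	aa_region	95	102	.	.	inframe_del	P95_R102del
TET2	NM_001127208.2	none	.	.	.	.	.	none
TP53	NM_000546.5	exact_aa	175	.	.	H	substitution	R175H
TP53	NM_000546.5	exact_aa	220	.	.	C	substitution	Y220C
TP53	NM_000546.5	exact_aa	245	.	.	S	substitution	G245S
TP53	NM_000546.5	exact_aa	248	.	.	Q,W	substitution	R248Q/W
TP53	NM_000546.5	exact_aa	273	.	.	C,H	substitution	R273C/H
TP53	NM_000546.5	exact_aa	282	.	.	W	substitution	R282W
U2AF1	NM_006758.2	exact_aa	34	.	.	F,Y	substitution	S34F/Y
U2AF1	NM_006758.2	exact_aa	157	.	.	P,R	substitution	Q157P/R
WT1	NM_024426.5	none	.	.	.	.	.	none
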