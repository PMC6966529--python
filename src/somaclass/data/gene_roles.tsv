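gene	role	tumour_category
ALK	oncogene	both
ASXL1	tumour_suppressor	both
BRAF	oncogene	both
BRCA1	tumour_suppressor	both
BRCA2	tumour_suppressor	both
CALR	oncogene	haematological
CEBPA	tumour_suppressor	haematological
CSF3R	oncogene	haematological
DNMT3A	tumour_suppressor	haematological
EGFR	oncogene	both
ESR1	oncogene	solid
EZH2	tumour_suppressor	haematological
FLT3	oncogene	haematological
GNAS	oncogene	solid
H3F3A	oncogene	solid
HRAS	oncogene	both
IDH1	oncogene	both
IDH2	oncogene	both
JAK2	oncogene	haematological
KIT	oncogene	both
KRAS	oncogene	both
MET	oncogene	solid
MPL	oncogene	haematological
NPM1	oncogene	haematological
NRAS	oncogene	both
PDGFRA	oncogene	both
RUNX1	tumour_suppressor	haematological
SETBP1	oncogene	haematological
SF3B1	oncogene	haematological
SRSF2	oncogene	haematological
TET2	tumour_suppressor	both
TP53	tumour_suppressor	both
U2AF1	oncogene	haematological
WT1	tumour_suppressor	haematological
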