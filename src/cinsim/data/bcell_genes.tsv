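# Curated B-cell development / B-cell activation / lymphocyte activation and
# hematopoietic progenitor differentiation genes with chromosomal location.
# Approximate curation from public annotation; used to derive the alpha track
# of the default fitness landscape.
gene	chrom
PAX5	9
EBF1	5
TCF3	19
IKZF1	7
IKZF3	17
RAG1	11
RAG2	11
DNTT	10
CD19	16
CD79A	19
CD79B	17
MS4A1	11
CD22	19
CD40	20
CD40LG	X
CD38	4
IL7R	5
IL7	8
FLT3	13
FLT3LG	19
KIT	4
KITLG	12
RUNX1	21
GATA3	10
GATA2	3
GATA1	X
TAL1	1
LMO2	11
LEF1	4
MYB	6
SPI1	11
BTK	X
BLNK	10
SYK	9
LYN	8
BLK	8
FYN	6
LCK	1
ZAP70	2
CD81	11
CR2	1
CD27	12
CD28	2
CTLA4	2
ICOS	2
TNFRSF13B	17
TNFRSF13C	22
TNFSF13B	13
PRDM1	6
XBP1	22
IRF4	6
IRF8	16
BCL6	3
BCL2	18
MCL1	1
BCL2L1	20
CIITA	16
CD74	5
HLA-DRA	6
IGHM	14
IGLL1	22
VPREB1	22
CD3D	11
CD3E	11
CD3G	11
CD4	12
CD8A	2
IL2	4
IL2RA	10
IL2RG	X
IL4	5
IL4R	16
IL10	1
IL21	4
IL21R	16
STAT5A	17
STAT5B	17
STAT6	12
JAK1	1
JAK3	19
NFKB1	4
NFKB2	10
REL	2
RELA	11
CARD11	7
CD5	11
CD6	11
CD2	1
CD48	1
SLAMF1	1
FCRL1	1
FCRL2	1
POU2AF1	11
POU2F2	19
BACH2	6
FOXO1	13
MEF2C	5
NOTCH2	1
DOCK8	9
WAS	X
AICDA	12
UNG	12
CD86	3
CD80	3
ITK	5
PLCG2	16
PIK3CD	1
PTPRC	1
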