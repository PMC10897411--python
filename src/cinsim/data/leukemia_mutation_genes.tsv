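# Curated genes recurrently somatically mutated in lymphoblastic leukemia,
# with chromosomal location (approximate curation from public annotation).
# Used to derive the beta track of the default fitness landscape; genes that
# also appear in bcell_genes.tsv are dropped by the builder so the two tracks
# stay disjoint.
gene	chrom
IKZF1	7
PAX5	9
TCF3	19
RUNX1	21
CDKN2A	9
CDKN2B	9
ETV6	12
TP53	17
NRAS	1
KRAS	12
FLT3	13
JAK2	9
JAK1	1
JAK3	19
IL7R	5
CRLF2	X
PTPN11	12
SH2B3	12
CREBBP	16
EP300	22
NSD2	4
KMT2A	11
KMT2D	12
SETD2	3
EZH2	7
TBL1XR1	3
ERG	21
MEF2D	1
ZNF384	12
DUX4	4
PBX1	1
ABL1	9
ABL2	1
PDGFRB	5
CSF1R	5
EPOR	19
NT5C2	10
PRPS1	X
TPMT	6
NUDT15	13
XPO1	2
USP7	16
CTCF	16
MYC	8
RB1	13
BTG1	12
NF1	17
PTEN	10
AKT1	14
PIK3CA	3
PIK3R1	5
FBXW7	4
NOTCH1	9
CDKN1B	12
ATM	11
BRAF	7
CBL	11
DNMT3A	2
TET2	4
ASXL1	20
SETBP1	18
GATA3	10
TLX1	10
TLX3	5
LMO1	11
HOXA9	7
MLLT1	19
MLLT3	9
AFF1	4
BCR	22
PTCH1	9
PHF6	X
WT1	11
SUZ12	17
EED	11
CTNNB1	3
MYCN	2
TCF7L2	10
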