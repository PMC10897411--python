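# Curated pan-cancer driver genes (oncogenes, tumor suppressors, frequently
# essential genes) with chromosomal location; approximate curation from public
# annotation. Used to derive the gamma (driver-density) track of the default
# fitness landscape.
gene	chrom
TP53	17
KRAS	12
EGFR	7
BRAF	7
PIK3CA	3
PTEN	10
APC	5
MYC	8
RB1	13
VHL	3
CDKN2A	9
SMAD4	18
ARID1A	1
KMT2C	7
KMT2D	12
NF1	17
ATM	11
BRCA1	17
BRCA2	13
ERBB2	17
ALK	2
RET	10
MET	7
KIT	4
IDH1	2
IDH2	15
NRAS	1
HRAS	11
CTNNB1	3
FBXW7	4
NOTCH1	9
EZH2	7
STK11	19
KEAP1	19
NFE2L2	2
SF3B1	2
U2AF1	21
SRSF2	17
DNMT3A	2
TET2	4
ASXL1	20
JAK2	9
MPL	1
CALR	19
CEBPA	19
RUNX1	21
GATA3	10
ESR1	6
AR	X
FOXA1	14
SPOP	17
CDH1	16
MAP3K1	5
GNAS	20
GNAQ	9
GNA11	19
SMO	7
PTCH1	9
SUFU	10
TSC1	9
TSC2	16
MTOR	1
RICTOR	5
RPTOR	17
AKT1	14
PIK3R1	5
ERBB3	12
FGFR1	8
FGFR2	10
FGFR3	4
PDGFRA	4
CDK4	12
CDK6	7
CCND1	11
CCNE1	19
MDM2	12
MDM4	1
BCL2	18
MCL1	1
TERT	5
ATRX	X
DAXX	6
MEN1	11
BAP1	3
PBRM1	3
SMARCA4	19
SMARCB1	22
STAG2	X
RAD21	8
POLE	12
POLD1	19
MSH2	2
MSH6	2
MLH1	3
PMS2	7
AXIN1	16
AXIN2	17
WRN	8
BLM	15
FANCA	16
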