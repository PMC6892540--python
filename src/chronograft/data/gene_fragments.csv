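gene,region,sites
A2AB,exon,603
ADORA3,exon,369
ADRB2,exon,846
APOB,exon,2523
APP,NC,636
ATP7,exon,723
BCHE,exon,1020
BDNF,exon,612
BMI1,NC,292
BRCA1,exon,3264
BRCA2,exon,4854
CNR1,exon,1017
COI,mtDNA,672
CREM,NC,350
CYTB,mtDNA,1167
DMP1,exon,1503
EDG1,exon,963
ENAM,exon,3477
FBN1,NC,669
GHR,exon,1044
IRBP,exon,1146
ND1,mtDNA,975
ND2,mtDNA,1074
PLCB4,NC,288
PNOC,exon,339
RAG1a,exon,1050
RAG1b,exon,1071
RAG2,exon,450
TTN,exon,4479
TYR1,exon,429
VWF,exon,1194
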