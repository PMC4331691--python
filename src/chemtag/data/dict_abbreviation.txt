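# ABBREVIATION gazetteer (case-sensitive), v1
5-FU
6-MP
ADP
ALA
AMP
ATP
AZT
BHA
BHT
BPA
CTAB
DDT
DEET
DHA
DMA
DMF
DMSO
DNA
DOPA
DTT
EDTA
EGCG
EGTA
EPA
FAD
FADH2
GDP
GSH
GTP
HEPES
LPS
LSD
MOPS
MSG
MTBE
MTX
NAD
NADH
NADP
NADPH
PAH
PEG
PETN
PTFE
PUFA
RDX
RNA
SDS
TBHQ
TCA
THC
TNT
cAMP
cGMP
dNTP
ssDNA
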