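gene	Saccharomyces_cerevisiae:POST_WGD	Saccharomyces_mikatae:POST_WGD	Saccharomyces_kudriavzevii:POST_WGD	Saccharomyces_uvarum:POST_WGD	Candida_glabrata:POST_WGD	Kazachstania_africana:POST_WGD	Kazachstania_naganishii:POST_WGD	Naumovozyma_castellii:POST_WGD	Naumovozyma_dairenensis:POST_WGD	Tetrapisispora_blattae:POST_WGD	Tetrapisispora_phaffii:POST_WGD	Vanderwaltozyma_polyspora:POST_WGD	Zygosaccharomyces_rouxii:PRE_WGD	Torulaspora_delbrueckii:PRE_WGD	Lachancea_kluyveri:PRE_WGD	Lachancea_thermotolerans:PRE_WGD	Lachancea_waltii:PRE_WGD	Kluyveromyces_lactis:PRE_WGD	Eremothecium_gossypii:PRE_WGD	Eremothecium_cymbalariae:PRE_WGD
CBF1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
NDC10	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
CEP3	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
CTF13	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
SKP1	2	2	2	2	2	2	2	2	2	2	2	2	1	1	1	1	1	1	1	1
CSE4	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
MIF2	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
OKP1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
AME1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
CTF19	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
MCM21	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
NKP1	1	1	1	1	1	1	1	0	0	1	1	1	1	1	1	1	1	1	0	0
NKP2	1	1	1	1	1	1	1	0	0	0	1	1	1	1	1	1	1	1	0	0
CHL4	1	1	1	1	1	1	1	0	0	1	1	1	1	1	1	1	1	1	1	1
IML3	1	1	1	1	1	1	1	0	0	1	1	1	1	1	1	1	1	1	0	0
CNN1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	1
WIP1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	0
MHF1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
MHF2	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
CTF3	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
MCM16	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
MCM22	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
NDC80	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
NUF2	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
SPC24	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
SPC25	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
MTW1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
NNF1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
NSL1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
DSN1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
SPC105	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
KRE28	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
DAM1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
DUO1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
DAD1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
DAD2	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
DAD3	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
DAD4	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
ASK1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
SPC34	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
SPC19	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
HSK3	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
STU2	2	2	2	2	2	2	2	2	2	2	2	2	1	1	1	1	1	1	1	1
BIK1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
BIM1	2	2	2	2	2	2	2	2	2	2	2	2	1	1	1	1	1	1	1	1
SLK19	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
CIN8	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
KIP1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
KIP3	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
KAR3	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
CIK1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
VIK1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
IPL1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
SLI15	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
BIR1	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	0	1
NBL1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
SGO1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
BUB1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
BUB3	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
MAD1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
MAD2	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
MAD3	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
MPS1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
FIN1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1
CDC20	2	2	2	2	2	2	2	2	2	2	2	2	1	1	1	1	1	1	1	1
CTF18	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
CTF4	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
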