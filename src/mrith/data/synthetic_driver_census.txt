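# Synthetic stand-in driver gene list (census-style subset; NOT the COSMIC census).
# Genes recurrently altered in small cell lung cancer and pan-cancer drivers.
TP53
RB1
EGFR
CREBBP
EP300
PTEN
PIK3CA
MYC
MYCN
MYCL
KMT2D
LRP1B
NOTCH1
NOTCH2
FGFR1
KIT
BRAF
KRAS
NF1
ARID1A
SMARCA4
APC
ATM
BRCA1
BRCA2
TERT
NTRK3
CDKN2A
STK11
IL7R
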