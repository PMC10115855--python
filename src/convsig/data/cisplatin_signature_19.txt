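ADAT2
ATP1B3
C1QBP
CDC7
CDCA7
CDIN1
FKBP14
KRT5
LRRC8C
LY6K
MMP10
NPM3
PSAT1
RIOK1
SLFN11
STOML2
USP31
WDR3
ZNF750
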