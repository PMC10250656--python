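symbol	inheritance
HPCA	AR
TH	AR
PRKRA	AR
COL6A3	AR
MECR	AR
PTS	AR
QDPR	AR
SLC6A3	AR
SLC30A10	AR
CP	AR
DDC	AR
SLC39A14	AR
SLC18A2	AR
SQSTM1	AR
VPS41	AR
COQ8A	AR
VPS11	AR
TSPOAP1	AR
MED27	AR
TOR1A	AD
TUBB4A	AD
THAP1	AD
PNKD	AD
SLC2A1	AD
PRRT2	AD
SGCE	AD
ATP1A3	AD
CIZ1	AD
CACNA1B	AD
ANO3	AD
GNAL	AD
KCTD17	AD
KMT2B	AD
RHOBTB2	AD
KCNA1	AD
CACNA1A	AD
YY1	AD
GNAO1	AD
GNB1	AD
SCN8A	AD
IRF2BPL	AD
NR4A2	AD
EIF2AK2	AD
DRD2	AD
VPS16	BOTH
SPR	BOTH
ADCY5	BOTH
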