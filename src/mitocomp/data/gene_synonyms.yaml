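# Gene-name normalization map: dialect symbol -> canonical symbol.
# Canonical set: ND1-6, ND4L, COI-III, ATP6, ATP8, CYTB, rrnL, rrnS,
# trnX (one-letter amino acid, with L1/L2 and S1/S2 disambiguated), CR.
# Keys are matched case-insensitively after stripping '-' and '_'.
COX1: COI
COX2: COII
COX3: COIII
CO1: COI
CO2: COII
CO3: COIII
COXI: COI
COXII: COII
COXIII: COIII
NAD1: ND1
NAD2: ND2
NAD3: ND3
NAD4: ND4
NAD4L: ND4L
NAD5: ND5
NAD6: ND6
NADH1: ND1
NADH2: ND2
NADH3: ND3
NADH4: ND4
NADH5: ND5
NADH6: ND6
COB: CYTB
CYB: CYTB
CYTB: CYTB
ATPASE6: ATP6
ATPASE8: ATP8
ATP6: ATP6
ATP8: ATP8
16S: rrnL
LRRNA: rrnL
RRN16: rrnL
RRNL: rrnL
12S: rrnS
SRRNA: rrnS
RRN12: rrnS
RRNS: rrnS
DLOOP: CR
CONTROLREGION: CR
ATRICHREGION: CR
TRNL(UUR): trnL2
TRNL(CUN): trnL1
TRNS(AGN): trnS1
TRNS(UCN): trnS2
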