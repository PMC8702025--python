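gene	strand
trnI	J
trnQ	N
trnM	J
ND2	J
trnW	J
trnC	N
trnY	N
COI	J
trnL2	J
COII	J
trnK	J
trnD	J
ATP8	J
ATP6	J
COIII	J
trnG	J
ND3	J
trnA	J
trnR	J
trnN	J
trnS1	J
trnE	J
trnF	N
ND5	N
trnH	N
ND4	N
ND4L	N
trnT	J
trnP	N
ND6	J
CYTB	J
trnS2	J
ND1	N
trnL1	N
rrnL	N
trnV	N
rrnS	N
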