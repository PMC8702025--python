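gene	kind	strand	start	end	start_codon	stop_codon	anticodon
trnI	tRNA	J	1	65			GAU
trnQ	tRNA	N	78	146			UUG
trnM	tRNA	J	180	243			CAU
ND2	PCG	J	244	1266	ATT	TAA
trnW	tRNA	J	1265	1332			UCA
trnC	tRNA	N	1325	1387			GCA
trnY	tRNA	N	1392	1454			GUA
COI	PCG	J	1420	2986	ATT	T
trnL2	tRNA	J	2988	3052			UAA
COII	PCG	J	3054	3741	ATG	T
trnK	tRNA	J	3742	3810			CUU
trnD	tRNA	J	3811	3876			GUC
ATP8	PCG	J	3877	4044	ATC	TAA
ATP6	PCG	J	4038	4715	ATG	TAA
COIII	PCG	J	4715	5503	ATG	TAA
trnG	tRNA	J	5503	5566			UCC
ND3	PCG	J	5567	5920	ATT	TAG
trnA	tRNA	J	5919	5981			UGC
trnR	tRNA	J	5982	6044			UCG
trnN	tRNA	J	6045	6109			GUU
trnS1	tRNA	J	6108	6172			GCU
trnE	tRNA	J	6173	6236			UUC
trnF	tRNA	N	6237	6300			GAA
ND5	PCG	N	6301	8035	ATG	T
trnH	tRNA	N	8037	8099			GUG
ND4	PCG	N	8100	9441	ATG	T
ND4L	PCG	N	9435	9731	ATG	TAA
trnT	tRNA	J	9734	9799			UGU
trnP	tRNA	N	9800	9862			UGG
ND6	PCG	J	9865	10383	ATT	TAA
CYTB	PCG	J	10383	11517	ATG	T
trnS2	tRNA	J	11518	11587			UGA
ND1	PCG	N	11606	12556	ATG	TAA
trnL1	tRNA	N	12558	12621			UAG
rrnL	rRNA	N	12622	13876
trnV	tRNA	N	13877	13947			UAC
rrnS	rRNA	N	13948	14727
CR	CR	J	14728	15274
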