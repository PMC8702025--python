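gene	kind	strand	start	end	start_codon	stop_codon	anticodon
trnI	tRNA	J	1	65			GAU
trnQ	tRNA	N	80	148			UUG
trnM	tRNA	J	161	225			CAU
ND2	PCG	J	226	1236	ATT	TAA
trnW	tRNA	J	1239	1306			UCA
trnC	tRNA	N	1299	1360			GCA
trnY	tRNA	N	1361	1424			GUA
COI	PCG	J	1390	2956	ATT	T
trnL2	tRNA	J	2957	3022			UAA
COII	PCG	J	3023	3710	ATG	T
trnK	tRNA	J	3711	3779			CUU
trnD	tRNA	J	3780	3846			GUC
ATP8	PCG	J	3847	4011	ATT	TAA
ATP6	PCG	J	4005	4682	ATG	TAA
COIII	PCG	J	4682	5470	ATG	TAA
trnG	tRNA	J	5469	5531			UCC
ND3	PCG	J	5532	5885	ATT	TAA
trnA	tRNA	J	6048	6112			UGC
trnR	tRNA	J	6278	6340			UCG
trnN	tRNA	J	6341	6405			GUU
trnS1	tRNA	J	6404	6467			GCU
trnE	tRNA	J	6468	6532			UUC
trnF	tRNA	N	6534	6596			GAA
ND5	PCG	N	6597	8331	ATG	T
trnH	tRNA	N	8333	8395			GUG
ND4	PCG	N	8396	9737	ATG	T
ND4L	PCG	N	9731	10027	ATG	TAA
trnT	tRNA	J	10030	10095			UGU
trnP	tRNA	N	10096	10157			UGG
ND6	PCG	J	10160	10675	ATT	TAA
CYTB	PCG	J	10688	11822	ATG	T
trnS2	tRNA	J	11823	11892			UGA
ND1	PCG	N	11921	12866	ATG	T
trnL1	tRNA	N	12868	12932			UAG
rrnL	rRNA	N	12933	14182
trnV	tRNA	N	14183	14252			UAC
rrnS	rRNA	N	14253	15033
CR	CR	J	15034	16031
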