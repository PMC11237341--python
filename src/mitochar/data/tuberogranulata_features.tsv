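name	type	start	end	strand	start_codon	stop_codon	anticodon	length	spacer_to_next
tRNA-Phe	tRNA	1	71	H			GAA	71	0
12S	rRNA	72	996	H				925	-4
tRNA-Val	tRNA	993	1063	H			TAC	71	14
16S	rRNA	1078	2671	H				1594	-2
tRNA-Leu2	tRNA	2670	2743	H			TAA	74	0
ND1	PCG	2744	3717	H	ATG	TA(A)		974	3
tRNA-Ile	tRNA	3721	3791	H			GAT	71	-1
tRNA-Gln	tRNA	3791	3862	L			TTG	72	-1
tRNA-Met	tRNA	3862	3930	H			CAT	69	0
ND2	PCG	3931	4971	H	ATT	TAG		1041	-2
tRNA-Trp	tRNA	4970	5038	H			TCA	69	0
tRNA-Ala	tRNA	5039	5107	L			TGC	69	0
tRNA-Asn	tRNA	5108	5180	L			GTT	73	2
OL	origin	5183	5212	H				30	-1
tRNA-Cys	tRNA	5212	5274	L			GCA	63	0
tRNA-Tyr	tRNA	5275	5341	L			GTA	67	1
COI	PCG	5343	6905	H	GTG	AGA		1563	-10
tRNA-Ser2	tRNA	6896	6966	L			TGA	71	3
tRNA-Asp	tRNA	6970	7037	H			GTC	68	0
COII	PCG	7038	7722	H	ATG	T(AA)		685	0
tRNA-Lys	tRNA	7723	7795	H			TTT	73	1
ATP8	PCG	7797	7961	H	ATG	TAA		165	-10
ATP6	PCG	7952	8634	H	ATG	TA(A)		683	-1
COIII	PCG	8634	9418	H	ATG	TA(A)		785	-1
tRNA-Gly	tRNA	9418	9486	H			TCC	69	0
ND3	PCG	9487	9831	H	ATG	TAG		345	-2
tRNA-Arg	tRNA	9830	9898	H			TCG	69	3
ND4L	PCG	9902	10198	H	ATG	TAA		297	-7
ND4	PCG	10192	11572	H	ATG	T(AA)		1381	0
tRNA-His	tRNA	11573	11641	H			GTG	69	0
tRNA-Ser1	tRNA	11642	11708	H			GCT	67	0
tRNA-Leu1	tRNA	11709	11781	H			TAG	73	0
ND5	PCG	11782	13599	H	ATG	TAA		1818	3
ND6	PCG	13603	14112	L	ATG	AGA		510	0
tRNA-Glu	tRNA	14113	14181	L			TTC	69	2
Cytb	PCG	14184	15323	H	ATG	TAG		1140	-1
tRNA-Thr	tRNA	15323	15392	H			TGT	70	1
tRNA-Pro	tRNA	15394	15462	L			TGG	69	-1
D-loop	control	15462	16841	H				1380	0
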