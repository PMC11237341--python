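name	type	start	end	strand	start_codon	stop_codon	anticodon	length	spacer_to_next
tRNA-Phe	tRNA	1	70	H			GAA	70	0
12S	rRNA	71	995	H				925	-4
tRNA-Val	tRNA	992	1061	H			TAC	70	3
16S	rRNA	1065	2658	H				1594	-2
tRNA-Leu2	tRNA	2657	2731	H			TAA	75	0
ND1	PCG	2732	3705	H	ATA	TA(A)		974	3
tRNA-Ile	tRNA	3709	3779	H			GAT	71	-1
tRNA-Gln	tRNA	3779	3850	L			TTG	72	-1
tRNA-Met	tRNA	3850	3918	H			CAT	69	0
ND2	PCG	3919	4959	H	ATG	TAG		1041	-2
tRNA-Trp	tRNA	4958	5026	H			TCA	69	0
tRNA-Ala	tRNA	5027	5095	L			TGC	69	0
tRNA-Asn	tRNA	5096	5168	L			GTT	73	2
OL	origin	5171	5198	H				28	-1
tRNA-Cys	tRNA	5198	5260	L			GCA	63	0
tRNA-Tyr	tRNA	5261	5327	L			GTA	67	1
COI	PCG	5329	6885	H	TTG	AGA		1557	-5
tRNA-Ser2	tRNA	6881	6951	L			TGA	71	3
tRNA-Asp	tRNA	6955	7021	H			GTC	67	0
COII	PCG	7022	7706	H	ATG	T(AA)		685	0
tRNA-Lys	tRNA	7707	7779	H			TTT	73	1
ATP8	PCG	7781	7945	H	ATG	TAA		165	-10
ATP6	PCG	7936	8618	H	ATG	TA(A)		683	-1
COIII	PCG	8618	9402	H	ATG	TA(A)		785	-1
tRNA-Gly	tRNA	9402	9470	H			TCC	69	0
ND3	PCG	9471	9815	H	TTG	TAG		345	-2
tRNA-Arg	tRNA	9814	9882	H			TCG	69	3
ND4L	PCG	9886	10182	H	ATG	TAA		297	-7
ND4	PCG	10176	11553	H	ATG	T(AA)		1378	6
tRNA-His	tRNA	11560	11628	H			GTG	69	6
tRNA-Ser1	tRNA	11635	11696	H			GCT	62	0
tRNA-Leu1	tRNA	11697	11769	H			TAG	73	0
ND5	PCG	11770	13587	H	ATG	TAA		1818	7
ND6	PCG	13595	14104	L	ATG	AGG		510	0
tRNA-Glu	tRNA	14105	14173	L			TTC	69	2
Cytb	PCG	14176	15315	H	ATG	TAG		1140	-1
tRNA-Thr	tRNA	15315	15385	H			TGT	71	0
tRNA-Pro	tRNA	15386	15454	L			TGG	69	0
D-loop	control	15455	16950	H				1496	0
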