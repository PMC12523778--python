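# Published gene annotation of the Typhlomys huangshanensis mitochondrial
# genome (GenBank PQ825598, voucher QLF1911102); 1-based inclusive
# coordinates on the circular molecule.
# Note: ND4's end is reconciled to the published length column (1383 nt);
# the publication's coordinate cell (11542) disagrees with its own length
# and regional totals by 5 nt.  See docs/methods.md.
# genome_length: 16497
name	from	to	strand	class
trnF	1	69	+	tRNA
rrnS	72	1026	+	rRNA
trnV	1026	1092	+	tRNA
rrnL	1093	2667	+	rRNA
trnL2	2668	2742	+	tRNA
ND1	2744	3700	+	PCG
trnI	3699	3767	+	tRNA
trnQ	3765	3836	-	tRNA
trnM	3836	3905	+	tRNA
ND2	3906	4949	+	PCG
trnW	4948	5015	+	tRNA
trnA	5021	5089	-	tRNA
trnN	5090	5163	-	tRNA
trnC	5196	5263	-	tRNA
trnY	5264	5327	-	tRNA
COX1	5329	6873	+	PCG
trnS2	6871	6939	-	tRNA
trnD	6943	7011	+	tRNA
COX2	7013	7696	+	PCG
trnK	7699	7763	+	tRNA
atp8	7765	7968	+	PCG
atp6	7926	8606	+	PCG
COX3	8606	9390	+	PCG
trnG	9390	9457	+	tRNA
ND3	9458	9805	+	PCG
trnR	9806	9874	+	tRNA
ND4L	9875	10171	+	PCG
ND4	10165	11547	+	PCG
trnH	11543	11610	+	tRNA
trnS1	11611	11669	+	tRNA
trnL1	11670	11739	+	tRNA
ND5	11740	13551	+	PCG
ND6	13553	14077	-	PCG
trnE	14079	14148	-	tRNA
Cytb	14154	15293	+	PCG
trnT	15296	15365	+	tRNA
trnP	15367	15433	-	tRNA
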