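# Indian gaur (Bos gaurus) reference mitogenome annotation, 16,345 bp.
# genome_length: 16345
# trnF anticodon: three of four sequenced animals carry GAA; sample GR01 carries AAA.
name	strand	start	end	feature_class	anticodon
trnF	H	1	67	tRNA	GAA
rrnS	H	68	1023	rRNA
trnV	H	1024	1090	tRNA	TAC
rrnL	H	1091	2659	rRNA
trnL2	H	2660	2734	tRNA	TAA
nad1	H	2737	3692	PCG
trnI	H	3693	3761	tRNA	GAT
trnQ	L	3759	3830	tRNA	TTG
trnM	H	3833	3901	tRNA	CAT
nad2	H	3902	4943	PCG
trnW	H	4944	5010	tRNA	TCA
trnA	L	5012	5080	tRNA	TGC
trnN	L	5082	5154	tRNA	GTT
trnC	L	5187	5253	tRNA	GCA
trnY	L	5254	5321	tRNA	GTA
cox1	H	5323	6867	PCG
trnS2	L	6865	6935	tRNA	TGA
trnD	H	6941	7008	tRNA	GTC
cox2	H	7010	7693	PCG
trnK	H	7697	7763	tRNA	TTT
atp8	H	7765	7965	PCG
atp6	H	7926	8606	PCG
cox3	H	8606	9389	PCG
trnG	H	9390	9458	tRNA	TCC
nad3	H	9459	9805	PCG
trnR	H	9806	9874	tRNA	TCG
nad4l	H	9875	10171	PCG
nad4	H	10165	11542	PCG
trnH	H	11543	11612	tRNA	GTG
trnS1	H	11613	11672	tRNA	GCT
trnL1	H	11674	11743	tRNA	TAG
nad5	H	11744	13564	PCG
nad6	L	13548	14075	PCG
trnE	L	14076	14144	tRNA	TTC
cob	H	14149	15288	PCG
trnT	H	15293	15361	tRNA	TGT
trnP	L	15361	15426	tRNA	TGG
control_region	H	15444	16345	control
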