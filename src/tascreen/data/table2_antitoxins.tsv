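Name	Isoform	Start	End	Strand	Length (nt)	Toxin mRNA Complementarity
MaTIA_0311	1	289493	289535	1	43	CDS
MaTIA_0311	2	289482	289535	1	54	CDS, 3′-UTR
MaTIA_0320	1	299493	299423	-1	71	CDS
MaTIA_0320	2	299517	299423	-1	95	CDS
MaTIA_0320	3	299574	299423	-1	152	CDS, 3′-UTR
MaTIA_1184	1	1096424	1096466	1	43	3′-UTR
MaTIA_1184	2	1096327	1096466	1	140	3′-UTR
MaTIA_1248	-	1152693	1152843	1	151	CDS, 5′-UTR
MaTIA_3336	1	3177829	3177749	-1	81	CDS, 3′-UTR
MaTIA_3336	2	3177945	3177749	-1	197	CDS, 3′-UTR
MaTIA_3390	1	3230318	3230458	1	141	CDS, 5′-UTR
MaTIA_3390	2	3230304	3230458	1	155	CDS, 5′-UTR
MaTIA_4017	1	3792450	3792505	1	56	CDS, 3′-UTR
MaTIA_4017	2	3792421	3792505	1	85	CDS, 3′-UTR
MaTIA_4253	-	4016466	4016717	1	252	CDS, 5′-UTR
MaTIA_4989	-	4737319	4737227	-1	93	CDS, 3′-UTR
MaTIA_5020	1	4768937	4768986	1	50	CDS, 3′-UTR
MaTIA_5020	2	4768892	4768986	1	95	CDS, 3′-UTR
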