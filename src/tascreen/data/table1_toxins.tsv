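Name	GenBank Accession	Start	End	Strand	Length (aa)	TM Regions
BH695_0311	ARI79592.1	289680	289489	-1	63	1
BH695_0320	ARI79601.1	299411	299551	1	46	1
BH695_1184	ARI80465.1	1096632	1096486	-1	48	1
BH695_1248	ARI80529.1	1152754	1152629	-1	41	1
BH695_3336	ARI82615.1	3177614	3177757	1	47	1
BH695_3390	ARI82669.1	3230378	3230259	-1	39	1
BH695_4017	ARI83296.1	3792667	3792476	-1	63	2
BH695_4253	ARI83532.1	4016545	4016411	-1	44	1
BH695_4989	ARI84268.1	4737004	4737249	1	81	2
BH695_5020	ARI84299.1	4769107	4768946	-1	53	1
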