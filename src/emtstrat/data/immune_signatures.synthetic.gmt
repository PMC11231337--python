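CTL	synthetic placeholder immune gene list	CD8A	CD8B	GZMA	GZMB	GZMH	GZMK	PRF1	IFNG	TNF	IL2	CXCL9	CXCL10	TBX21	EOMES	KLRG1	NKG7	GNLY	FASLG	LAMP1	CST7
Treg	synthetic placeholder immune gene list	FOXP3	CTLA4	IL2RA	IKZF2	TNFRSF18	TNFRSF4	TNFRSF9	LAG3	TIGIT	CCR8	CD4	IL10	TGFB1	ENTPD1	NT5E	LRRC32	BATF	SOCS1	CCR4	ICOS
M1	synthetic placeholder immune gene list	NOS2	IL12A	IL12B	IL1B	IL6	CXCL11	CD80	CD86	FCGR1A	SOCS3	IRF1	IRF5	KYNU	CCL5	CCR7	IDO1	PTGS2	HLA-DRA	TLR2	TLR4
M2	synthetic placeholder immune gene list	CD163	MRC1	MSR1	ARG1	CCL17	CCL22	CCL24	TGM2	CD209	F13A1	STAB1	MARCO	VEGFA	MMP14	LYVE1	SIGLEC1	IL4R	CLEC7A	CHI3L1	CCL13
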