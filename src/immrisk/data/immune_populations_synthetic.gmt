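B cells	synthetic stand-in marker set	CD19	MS4A1	CD79A	CD79B	BLK	TCL1A	SPIB	BLNK	FCRL2	PNOC	ABCB4	COCH
Eosinophils	synthetic stand-in marker set	IL5RA	CCR3	EPX	PRG2	SIGLEC8	CLC	GATA1	HRH4	THBS1	CYSLTR2
Macrophages	synthetic stand-in marker set	CD68	CD163	CSF1R	MSR1	MRC1	FCGR1A	MARCO	APOE	LYZ	CHIT1	SCG5
Mast cells	synthetic stand-in marker set	TPSAB1	TPSB2	CPA3	MS4A2	KIT	CMA1	HDC	SLC18A2	GATA2	CTSG
NK CD56bright cells	synthetic stand-in marker set	NCAM1	XCL1	XCL2	KLRC1	GZMK	SELL	FOXJ1	MPPED1	PLA2G6
NK CD56dim cells	synthetic stand-in marker set	FCGR3A	KIR2DL1	KIR2DL3	KIR3DL1	GZMB	PRF1	SPON2	IL21R	KIR2DS1
Neutrophils	synthetic stand-in marker set	FCGR3B	CSF3R	CEACAM3	FPR1	S100A8	S100A9	CXCR2	ELANE	MPO	CEACAM8
T helper cells	synthetic stand-in marker set	CD4	CD28	ICOS	IL7R	ANP32B	BATF	NUP107	PHF10	TSHZ1
Tcm cells	synthetic stand-in marker set	CCR7	CD27	TCF7	LEF1	AQP3	ATF7IP	ATM	CASP8	CLUAP1	DOCK9
Tem cells	synthetic stand-in marker set	GZMA	CCR5	CXCR3	IL2RB	KLRG1	AKT3	CCR2	EWSR1	LTK	NFATC4
Tfh cells	synthetic stand-in marker set	CXCR5	BCL6	PDCD1	IL21	CD200	SH2D1A	CHGB	HEY1	MAF	MYO6
aDCs	synthetic stand-in marker set	LAMP3	CD83	CCL19	CCL22	IDO1	OAS3	EBI3	INDO1
iDCs	synthetic stand-in marker set	CD1A	CD1B	CD1C	CD1E	ITGAX	NRP1	CLEC10A	FCER1A	FABP4	CD101	MMP12	SYT17
Activated CD8 T cells	synthetic stand-in marker set	CD8A	CD8B	GZMM	FLT3LG	LIME1	DNAJB1	MPZL1	THUMPD1	ZEB1
Gamma delta T cells	synthetic stand-in marker set	TRGV9	TRDV2	CD160	FEZ1	TARP	STMN3	CDR2	CELSR3
Tregs	synthetic stand-in marker set	FOXP3	IL2RA	CTLA4	IKZF2	CCR8	TNFRSF18	LRRC32	HPGD
Cytotoxic cells	synthetic stand-in marker set	GNLY	KLRB1	KLRD1	NKG7	CTSW	KLRK1	APBA2	CTSL	DUSP2	RUNX3
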