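MOFFITT_CLASSICAL	classical PDAC marker genes	BTNL8	FAM3D	ATAD4	AGR3	CTSE	LOC400573	LYZ	TFF2	TFF1	ANXA10	LGALS4	PLA2G10	CEACAM6	VSIG2	TSPAN8	ST6GALNAC1	AGR2	TFF3	CYP3A7	MYO1A	CLRN3	KRT20	CDH17	SPINK4	REG4
MOFFITT_BASAL	basal-like PDAC marker genes	VGLL1	UCA1	S100A2	LY6D	SPRR3	SPRR1B	LEMD1	KRT15	CTSL2	DHRS9	AREG	CST6	SERPINB3	KRT6C	KRT6A	SERPINB4	FAM83A	SCEL	FGFBP1	KRT7	KRT17	GPR87	TNS4	SLC2A1	ANXA8L2
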