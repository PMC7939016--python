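IES_CYTOLYTIC_ACTIVITY	reconstructed cytolytic activity set	GZMA	PRF1	GZMB	GZMH	GNLY
IES_CD8_T_CELL	reconstructed CD8+ T cell set	CD8A	CD8B	GZMK	EOMES	CD3D	CD3E
IES_TYPE_I_IFN	reconstructed type I interferon response set	MX1	MX2	OAS1	OAS2	OAS3	ISG15	IFI44L	IFIT1	IFIT3	IRF7	STAT2
IES_MACROPHAGE	reconstructed macrophage set	CD68	CD163	CD84	MS4A4A	MSR1	MRC1	CSF1R
IES_TCELL_COINHIBITION	reconstructed T-cell co-inhibition set	CTLA4	PDCD1	LAG3	BTLA	TIGIT	HAVCR2	CD274	PDCD1LG2	CD276
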