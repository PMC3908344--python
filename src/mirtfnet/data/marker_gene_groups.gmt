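unique_SCLC	genes of the small-cell cohort network	RB1	E2F1	E2F2	CCNT2	CMYC	CEBPA	TP53	CDKN2A	HDAC4
common_SCLC_NSCLC	genes shared by the small-cell and non-small-cell networks	RB1	E2F1	E2F2	CCNT2	CMYC	CEBPA	TP53	CDKN2A	HDAC4
common_all	genes shared by all three cohort networks	RB1	E2F1	E2F2	CCNT2	CMYC	CEBPA	TP53	CDKN2A	HDAC4
common_NSCLC_general	genes shared by the non-small-cell and general-path networks only	TFDP2	AHR	CCND1	TP73	RBL2	TAF1	PML	BCL6	MYB	WT1	PARP1	PCAF	TWIST	MCM7
NSCLC_specific	genes found only in the non-small-cell network	E2F6	TFDP1	SUV39H1	HNRPD
general_specific	genes found only in the general-path network	RBL1	IRF1	HMGA1
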