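FATTY_ACID_BETA_OXIDATION	mitochondrial long- and short-chain fatty acid beta-oxidation	ACADVL	HADH	ECH1	ECI1	ECI2	ACAT1	DECR1	HSD17B10	ACOT13	GCDH
KETONE_BODY_METABOLISM	ketone body synthesis and utilization	OXCT1	ACAT1	HMGCS2	BDH1
ONE_CARBON_METABOLISM	mitochondrial one-carbon and folate metabolism	MTHFD2	MTHFD2L	SHMT2	FAHD1	DLD	GATM
MITO_TRANSLATION	mitochondrial ribosome and translation initiation	MRPL1	MRPL10	MRPL12	MRPL14	MTIF3	TFB1M	DARS2	PNPT1	TFAM
MITO_IMPORT_ASSEMBLY	mitochondrial protein import and respiratory chain assembly	TOMM20	SCO2	NDUFB6	COX5A	ATP5PO	HSPA9
MITO_STRESS_RESPONSE	mitochondrial chaperones and redox buffering	PRDX3	HSPD1	HSPE1	GSTK1	PPIF
TCA_CYCLE	tricarboxylic acid cycle	CS	MDH2	DLD	FAHD1	OGDH	SDHA
CREATINE_ENERGY_BUFFERING	creatine kinase energy shuttle	CKMT1A	CKMT1B	GATM	CKB
MITO_DYNAMICS_TRAFFICKING	mitochondrial dynamics, autophagy and trafficking	RHOT1	RAB24	MFN2	OPA1
NUCLEOTIDE_METABOLISM	mitochondrial nucleotide metabolism	NT5DC3	NT5M	MCEE	ACSF2
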