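drug	target	indication
Regorafenib	RET
Regorafenib	FLT1
Regorafenib	KDR
Regorafenib	KIT
Regorafenib	PDGFRA
Regorafenib	PDGFRB
Regorafenib	FGFR1
Regorafenib	TEK
Regorafenib	NTRK1
Regorafenib	EPHA2
Regorafenib	ABL1
Tamoxifen	ESR1
Tamoxifen	ESR2
Tamoxifen	PRKCA
Tamoxifen	PRKCB
Tamoxifen	PRKCD
Tamoxifen	PRKCE
Tamoxifen	PRKCG
Tamoxifen	PRKCQ
Tamoxifen	PRKCZ
Tamoxifen	ESRRG
Ponatinib	ABL1
Ponatinib	KIT
Ponatinib	RET
Ponatinib	TEK
Ponatinib	FGFR1
Ponatinib	LCK
Ponatinib	SRC
Ponatinib	LYN
Ponatinib	KDR
Ponatinib	PDGFRA
Dasatinib	ABL1
Dasatinib	SRC
Dasatinib	FYN
Dasatinib	LCK
Dasatinib	KIT
Dasatinib	PDGFRB
Dasatinib	EPHA2
Dasatinib	BTK
Dasatinib	FGR
Dasatinib	LYN
Imatinib	PDGFRB
Imatinib	ABL1
Imatinib	KIT
Imatinib	RET
Imatinib	NTRK1
Imatinib	CSF1R
Imatinib	PDGFRA
Brigatinib	EGFR
Brigatinib	ABL1
Brigatinib	IGF1R
Brigatinib	INSR
Brigatinib	MET
Brigatinib	ERBB2
Sorafenib	PDGFRB
Sorafenib	KIT
Sorafenib	KDR
Sorafenib	FGFR1
Sorafenib	RET
Sorafenib	FLT1
Sunitinib	PDGFRB
Sunitinib	FLT1
Sunitinib	KDR
Sunitinib	KIT
Sunitinib	CSF1R
Sunitinib	PDGFRA
Nintedanib	FLT1
Nintedanib	KDR
Nintedanib	FGFR1
Nintedanib	LCK
Nintedanib	LYN
Nintedanib	SRC
Pazopanib	FLT1
Pazopanib	KDR
Pazopanib	PDGFRA
Pazopanib	PDGFRB
Pazopanib	KIT
Midostaurin	PRKCA
Midostaurin	KDR
Midostaurin	KIT
Midostaurin	PDGFRA
Midostaurin	PDGFRB
Resveratrol	ITGA5
Resveratrol	ITGB3
Resveratrol	SNCA
Resveratrol	ESR1
Resveratrol	AKT1
Diethylstilbestrol	ESR1
Diethylstilbestrol	ESRRG
Diethylstilbestrol	ESR2
Diethylstilbestrol	ESRRA
Tofacitinib	TYK2
Tofacitinib	JAK2
Tofacitinib	JAK1
Tofacitinib	JAK3
Lenvatinib	FLT1
Lenvatinib	KDR
Lenvatinib	FGFR1
Lenvatinib	KIT
Foreskin fibroblast (neonatal)	FLT1
Foreskin fibroblast (neonatal)	CSF2RA
Foreskin fibroblast (neonatal)	PDGFRB
Foreskin fibroblast (neonatal)	TGFB1
Baricitinib	JAK1
Baricitinib	JAK2
Baricitinib	PTK2B
Baricitinib	JAK3
Foreskin keratinocyte (neonatal)	EGFR
Foreskin keratinocyte (neonatal)	CSF2RA
Foreskin keratinocyte (neonatal)	PDGFRA
Foreskin keratinocyte (neonatal)	TGFB1
Bosutinib	ABL1
Bosutinib	LYN
Bosutinib	SRC
Estradiol valerate	ESR1
Estradiol valerate	ESR2
Estradiol valerate	ESRRG
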