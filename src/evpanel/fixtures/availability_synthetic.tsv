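group	marker
healthy	A2M
healthy	CKM
healthy	FLNA
healthy	FLNC
healthy	HP
healthy	ITGA2B
healthy	MAN2B1
healthy	ORM2
healthy	PLTP
healthy	QSOX1
healthy	TGM2
healthy	TLN1
early	A2M
early	CKM
early	FLNA
early	FLNC
early	HP
early	HSP70
early	ITGA2B
early	MAN2B1
early	ORM2
early	PF4
early	PLTP
early	QSOX1
early	TGM2
late	A2M
late	CKM
late	FLNA
late	FLNC
late	HSP70
late	ITGA2B
late	MAN2B1
late	ORM2
late	PF4
late	PLTP
late	TGM2
late	TLN1
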