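sample_id	response	os_time	os_event	stage	grade
324_012_012	pCR	.	.	IIB	3
367_005_005	pCR	.	.	IIIB	3
402_006_006	pCR	.	.	IIIB	3
485_004_004	pCR	.	.	IIIB	3
524_006_006	pCR	.	.	IIA	3
557_012_012	pCR	.	.	IIIB	3
658_004_004	pCR	.	.	IIIB	3
661_005_005	pCR	.	.	IIB	3
665_006_006	pCR	.	.	IIB	3
692_004_004	pCR	.	.	IIIB	2
696_005_005	pCR	.	.	IIB	3
735_012_012	pCR	.	.	IIB	3
805_005_005	pCR	.	.	IIB	2
M211_006_006	pCR	.	.	IIIA	3
M571_004_004	pCR	.	.	IIB	3
M635_005_005	pCR	.	.	IIIC	3
M750_006_006	pCR	.	.	IIIA	3
M792_012_012	pCR	.	.	IIIA	3
757_004_004	RCB-I	.	.	IIIB	2
348_004_004	RCB-II	.	.	IIIA	3
494_005_005	RCB-II	.	.	IIA	3
681_012_012	RCB-II	.	.	IIB	3
219_005_005	RCB-III	.	.	IIIB	3
229_006_006	RCB-III	.	.	IIIA	3
612_006_006	RCB-III	.	.	IIIA	3
732_006_006	RCB-III	.	.	IIIA	3
M345_012_012	RCB-III	.	.	IIIB	3
125_004_004	RD	.	.	IIA	3
406_012_012	RD	.	.	IIIA	3
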