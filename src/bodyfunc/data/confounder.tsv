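surface	category	concept_id	semantic_types	polarity
pain	CONFOUNDER	22253000	T184
pain score	CONFOUNDER	22253000	T184
vision	CONFOUNDER	281004001	T039
visual acuity	CONFOUNDER	363983007	T039
20/20	CONFOUNDER
20/40	CONFOUNDER
slr	CONFOUNDER	275913000	T060
straight leg raise	CONFOUNDER	275913000	T060
blood pressure	CONFOUNDER	75367002	T201
pulse	CONFOUNDER	8499008	T201
heart rate	CONFOUNDER	364075005	T201
temperature	CONFOUNDER	386725007	T201
respiratory rate	CONFOUNDER	86290005	T201
tone	CONFOUNDER	43029002	T039
muscle tone	CONFOUNDER	43029002	T039
balance	CONFOUNDER	282859009	T039
coordination	CONFOUNDER	85563006	T039
hearing	CONFOUNDER	47078008	T039
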