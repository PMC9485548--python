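surface	category	concept_id	semantic_types	polarity
strength	STRENGTH	44432004	T039
muscle strength	STRENGTH	44432004	T039
motor strength	STRENGTH	44432004	T039
grip strength	STRENGTH	44432004	T039
muscle power	STRENGTH	44432004	T039
extraocular movements	STRENGTH	44432004	T039
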