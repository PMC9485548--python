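surface	category	concept_id	semantic_types	polarity
history	SECTION_FILTER
past medical history	SECTION_FILTER
medical history	SECTION_FILTER
social history	SECTION_FILTER
family history	SECTION_FILTER
plan	SECTION_FILTER
plan of care	SECTION_FILTER
medications	SECTION_FILTER
chief complaint	SECTION_FILTER
chief complaints	SECTION_FILTER
claimant alleges	SECTION_FILTER
rx	SECTION_FILTER
subjective	SECTION_FILTER
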