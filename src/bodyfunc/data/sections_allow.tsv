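surface	category	concept_id	semantic_types	polarity
motor	SECTION_ALLOW
motor exam	SECTION_ALLOW
reflexes	SECTION_ALLOW
reflexes exam	SECTION_ALLOW
range of motion	SECTION_ALLOW
rom	SECTION_ALLOW
neuro	SECTION_ALLOW
neurological	SECTION_ALLOW
neurologic	SECTION_ALLOW
physical exam	SECTION_ALLOW
physical examination	SECTION_ALLOW
musculoskeletal	SECTION_ALLOW
strength	SECTION_ALLOW
muscle strength	SECTION_ALLOW
extremities	SECTION_ALLOW
objective	SECTION_ALLOW
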