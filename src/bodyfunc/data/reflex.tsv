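surface	category	concept_id	semantic_types	polarity
reflex	REFLEX	87572000	T039
deep tendon reflexes	REFLEX	87572000	T039
dtr	REFLEX	87572000	T039
patellar reflex	REFLEX	87572000	T039
biceps reflex	REFLEX	87572000	T039
achilles reflex	REFLEX	87572000	T039
plantar	REFLEX	87572000	T039
babinski	REFLEX	87572000	T039
clonus	REFLEX	87572000	T039
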