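surface	category	concept_id	semantic_types	polarity
decreased	QUALIFIER	C0205216	T080	-1
impaired	QUALIFIER	C0221099	T080	-1
limited	QUALIFIER	C0439801	T080	-1
reduced	QUALIFIER	C0392756	T080	-1
diminished	QUALIFIER	C0392756	T080	-1
weak	QUALIFIER	C3714552	T080	-1
absent	QUALIFIER	C0332197	T080	-1
poor	QUALIFIER	C0542537	T080	-1
restricted	QUALIFIER	C0443288	T080	-1
full	QUALIFIER	C0443225	T080	1
normal	QUALIFIER	C0205307	T080	1
intact	QUALIFIER	C0205266	T080	1
brisk	QUALIFIER	C0560087	T080	1
preserved	QUALIFIER	C0205281	T080	1
trace	QUALIFIER	C0336951	T080
fair	QUALIFIER	C0424576	T080
symmetric	QUALIFIER	C0332516	T080
equal	QUALIFIER	C0205163	T080
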