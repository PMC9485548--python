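surface	category	concept_id	semantic_types	polarity
range of motion	ROM	364564000	T039
rom	ROM	364564000	T039
f-rom	ROM	364564000	T039
flexion	ROM	364564000	T039
extension	ROM	364564000	T039
abduction	ROM	364564000	T039
adduction	ROM	364564000	T039
dorsiflexion	ROM	364564000	T039
plantar flexion	ROM	C0231784	T039
rotation	ROM	364564000	T039
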