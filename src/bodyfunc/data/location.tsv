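surface	category	concept_id	semantic_types	polarity
arm	LOCATION	53120007	T023
shoulder	LOCATION	16982005	T023
knee	LOCATION	72696002	T023
elbow	LOCATION	127949000	T023
wrist	LOCATION	74670003	T023
hip	LOCATION	29836001	T023
ankle	LOCATION	344001	T023
hand	LOCATION	85562004	T023
foot	LOCATION	56459004	T023
leg	LOCATION	30021000	T023
neck	LOCATION	45048000	T023
spine	LOCATION	421060004	T023
cervical	LOCATION	81105003	T023
cervical spine	LOCATION	122494005	T023
lumbar spine	LOCATION	122496007	T023
upper extremity	LOCATION	53120007	T023
lower extremity	LOCATION	61685007	T023
biceps	LOCATION	85050009	T023
triceps	LOCATION	57507008	T023
quadriceps	LOCATION	43899006	T023
hamstring	LOCATION	81167006	T023
deltoid	LOCATION	32360004	T023
great toe	LOCATION	83738005	T023
eyelid	LOCATION	80243003	T023
toes	LOCATION	29707007	T023
fingers	LOCATION	7569003	T023
left	LOCATION		T082
right	LOCATION		T082
bilateral	LOCATION		T082
bilaterally	LOCATION		T082
both	LOCATION		T082
proximal	LOCATION		T082
distal	LOCATION		T082
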