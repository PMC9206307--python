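phrase	category	polarity	match_mode
anxiety	theme:symptoms	-1	exact-token
agitation	theme:symptoms	-1	exact-token
anger	theme:symptoms	-1	exact-token
nervousness	theme:symptoms	-1	exact-token
anxious	theme:symptoms	-1	exact-token
sad	theme:symptoms	-1	exact-token
calmness	theme:symptoms	1	exact-token
composure	theme:symptoms	1	exact-token
interaction	theme:social	1	exact-token
participation	theme:social	1	exact-token
engagement	theme:social	1	exact-token
isolation	theme:social	-1	exact-token
withdrawal	theme:social	-1	exact-token
energy	theme:wellbeing	1	exact-token
appetite	theme:wellbeing	1	exact-token
vitality	theme:wellbeing	1	exact-token
exhaustion	theme:wellbeing	-1	exact-token
fatigue	theme:wellbeing	-1	exact-token
satisfaction	theme:experience	1	exact-token
motivation	theme:experience	1	exact-token
optimism	theme:experience	1	exact-token
complaints	theme:experience	-1	exact-token
frustration	theme:experience	-1	exact-token
more	change	1	exact-token
increase	change	1	exact-token
increased	change	1	exact-token
increases	change	1	exact-token
improvement	change	1	exact-token
improved	change	1	exact-token
less	change	-1	exact-token
fewer	change	-1	exact-token
decrease	change	-1	exact-token
decreased	change	-1	exact-token
reduction	change	-1	exact-token
reduced	change	-1	exact-token
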