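trigger	kind	scope	window
not	negation	forward	sentence
no	negation	forward	sentence
never	negation	forward	sentence
without	negation	forward	sentence
denies	negation	forward	sentence
if	hypothetical	forward	sentence
possibly	hypothetical	forward	sentence
might	hypothetical	forward	sentence
could	hypothetical	forward	sentence
in case	hypothetical	forward	sentence
mother	non-patient-experiencer	forward	sentence
father	non-patient-experiencer	forward	sentence
sister	non-patient-experiencer	forward	sentence
brother	non-patient-experiencer	forward	sentence
family	non-patient-experiencer	forward	sentence
wife	non-patient-experiencer	forward	sentence
husband	non-patient-experiencer	forward	sentence
years ago	non-current	bidirectional	sentence
in the past	non-current	bidirectional	sentence
previously	non-current	forward	sentence
history of	non-current	forward	sentence
but	terminator
however	terminator
;	terminator
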