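trigger	kind	scope	window
niet	negation	forward	sentence
geen	negation	forward	sentence
nooit	negation	forward	sentence
zonder	negation	forward	sentence
als	hypothetical	forward	sentence
indien	hypothetical	forward	sentence
mogelijk	hypothetical	forward	sentence
misschien	hypothetical	forward	sentence
moeder	non-patient-experiencer	forward	sentence
vader	non-patient-experiencer	forward	sentence
zus	non-patient-experiencer	forward	sentence
broer	non-patient-experiencer	forward	sentence
familie	non-patient-experiencer	forward	sentence
vroeger	non-current	bidirectional	sentence
jaren geleden	non-current	bidirectional	sentence
in het verleden	non-current	bidirectional	sentence
maar	terminator
;	terminator
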