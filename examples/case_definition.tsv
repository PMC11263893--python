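# Dementia cohort definition: diagnosis-code prefixes (trailing wildcard
# implied) and medication-name substrings.  Edit freely; the CLI accepts
# this file via --case-definition.
diagnosis	331.0*
diagnosis	G30.*
diagnosis	290.4*
diagnosis	F01.*
diagnosis	331.1*
diagnosis	G31.0*
diagnosis	331.82
diagnosis	G31.83
diagnosis	290.0*
diagnosis	290.1*
diagnosis	290.8*
diagnosis	290.9*
medication	aricept
medication	donepezil
medication	razadyne
medication	reminyl
medication	galantamine
medication	exelon
medication	rivastigmine
medication	namenda
medication	memantine
medication	acetylcholine
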