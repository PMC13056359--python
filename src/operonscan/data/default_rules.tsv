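category	priority	pattern	scope
cooC	10	\bcooc|co[- ]dehydrogenase (maturation|nickel[- ]insertion) (factor|protein)|carbon monoxide dehydrogenase accessory	any
cooT	11	\bcoot|nickel[- ]binding protein.*coot	any
cooJ	12	\bcooj	any
ferredoxin	20	ferredoxin|flavodoxin	any
hydrogenase_maturase	25	(?<!de)hydrogenase (maturation|expression|formation|nickel incorporation|isoenzymes formation)|\bhyp[a-fx]\b|\bhyci\b	any
one_carbon_pool	30	formate dehydrogenase|acetyl-coa (synthase|decarbonylase)|carbon[- ]monoxide dehydrogenase/acetyl|tetrahydrofolate|corrinoid|cofesp|methanofuran|methylene-thf|formate--|glycine cleavage	any
abc_transporter	35	abc[- ]transporter|abc[- ]type	any
transcription_regulation	40	transcription(al)?[- ](regulator|factor|repressor|activator|antiterminator)|rna polymerase sigma|dna[- ]binding (transcription|response) regulator|helix-turn-helix.*regulator	any
nadp_fad_oxidoreductase	45	(nad\(?p?\)?h?|fad|fmn|flavin)[^\t]*oxidoreductase|oxidoreductase[^\t]*(nad|fad|fmn|flavin)|\bnadh dehydrogenase|flavoprotein	any
hydrogenase	50	(?<!de)hydrogenase	any
fes_protein	55	iron[- ]sulfur|\bfe[- ]?s\b cluster|\b[24]fe[- ]?[24]s\b|\bcoof\b|\bsuf[a-fsu]\b|\bisc[aursx]\b	any
other_regulation	60	regulat|anti-?sigma|two[- ]component|response regulator|histidine kinase|serine/threonine[- ]protein (kinase|phosphatase)|\bgaf\b|\bpas\b domain	any
transporter	65	transporter|permease|efflux|antiporter|symporter|\buptake\b|\bchannel\b|sodium/solute	any
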