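# Character matrix: 9 solifuges plus the hypothetical all-zero outgroup.
Outgroup	00000
Ammotrechula_mulaiki	00???
Eberlanzia_flava	10000
Eremobates_pallipes	10000
Eremobates_similis	10000
Gluvia_dorsalis	60??0
Gnosippus_sp	40???
Paragaleodes_pallidus	51111
Rhagodes_sp	31??1
Solpugista_sp	20000
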