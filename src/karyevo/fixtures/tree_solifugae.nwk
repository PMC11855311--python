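(Outgroup,(((Eremobates_pallipes,Eremobates_similis),(Paragaleodes_pallidus,Rhagodes_sp)),(Ammotrechula_mulaiki,((Gluvia_dorsalis,(Eberlanzia_flava,Gnosippus_sp)),Solpugista_sp))));
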