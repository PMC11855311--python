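# Character matrix: 10 thelyphonids plus the hypothetical all-zero outgroup.
Outgroup	000000
Ginosigma_sp	300000
Hypoctonus_cf_gastrostictus	120000
Labochirus_proboscideus	000??0
Mastigoproctus_giganteus	620000
Thelyphonus_cf_linganus	121??0
Thelyphonus_sepiaris	201??0
Typopeltis_crucifer	3?????
Typopeltis_guangxiensis	510200
Uroproctus_assamensis	000000
Yekuana_venezolensis	410100
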