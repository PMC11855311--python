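# Character matrix: 11 schizomids plus the hypothetical all-zero outgroup.
Outgroup	0000
Agastoschizomus_lucifer	0000
Clavizomus_sp	00??
Hubbardiidae_Cameroon	0001
Hubbardiidae_Seychelles	0000
Notozomus_sp	00??
Olmecazomus_brujo	0001
Orientzomus_Luzon	21??
Orientzomus_Mindanao	2?00
Rowlandius_ubajara	00??
Rowlandius_sp	10??
Stenochrus_sp	00??
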