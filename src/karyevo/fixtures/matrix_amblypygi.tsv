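# Character matrix: 24 amblypygids plus the hypothetical all-zero outgroup.
Outgroup	00000
Acanthophrynus_coronatus	12000
Charon_cf_grayi	30101
Charinus_cavernicolus	00???
Charinus_dominicanus	A2???
Charinus_neocaledonicus	00000
Charinus_pescotti	00000
Damon_medius	3?100
Euphrynichus_amanica	01200
Euphrynichus_bacillifer	72020
Heterophrynus_cf_elaphus	00000
Heterophrynus_longicornis	52100
Paraphrynus_aztecus	B2???
Paraphrynus_carolynae	E2???
Paraphrynus_cubensis	C2???
Paraphrynus_mexicanus	F2020
Paraphrynus_pseudomexicanus	D1???
Paraphrynus_robustus	62???
Phrynichus_ceylonicus	82200
Phrynus_marginemaculatus	42???
Sarax_aff_batuensis	71???
Sarax_huberi	92???
Sarax_ioanniticus	20???
Sarax_seychellarum	G2010
Sarax_brachydactylus	00???
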