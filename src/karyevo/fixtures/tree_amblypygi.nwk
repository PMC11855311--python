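(Outgroup,((Charon_cf_grayi,((Charinus_cavernicolus,(Charinus_neocaledonicus,(Charinus_dominicanus,Charinus_pescotti))),(Sarax_ioanniticus,((Sarax_seychellarum,Sarax_huberi),(Sarax_aff_batuensis,Sarax_brachydactylus))))),((Damon_medius,((Euphrynichus_amanica,Euphrynichus_bacillifer),Phrynichus_ceylonicus)),((Heterophrynus_cf_elaphus,Heterophrynus_longicornis),(Acanthophrynus_coronatus,(Phrynus_marginemaculatus,(Paraphrynus_robustus,(Paraphrynus_aztecus,(Paraphrynus_cubensis,(Paraphrynus_pseudomexicanus,(Paraphrynus_carolynae,Paraphrynus_mexicanus)))))))))));
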