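# Character matrix: 3 ricinuleids plus the hypothetical all-zero outgroup.
Outgroup	0000
Cryptocellus_narino	1100
Pseudocellus_gertschi	0110
Ricinoides_olounoua	0010
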