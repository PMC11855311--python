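(Outgroup,(Ricinoides_olounoua,(Cryptocellus_narino,Pseudocellus_gertschi)));
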