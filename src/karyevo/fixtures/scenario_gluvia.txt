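# Derivation of the Gluvia dorsalis composition (five acrocentric pairs, the
# two largest much longer; 2n = 10) from a Solpugista-like ten-pair acrocentric
# set by five tandem fusions (each of the ten pairs fuses pairwise).
start: a=10
sizes: 1.95,1.76,0.90,0.86,0.81,0.77,0.74,0.70,0.66,0.63
event: tandem_fusion a+a @ 0,2
event: tandem_fusion a+a @ 0,1
event: tandem_fusion a+a @ 0,1
event: tandem_fusion a+a @ 0,1
event: tandem_fusion a+a @ 0,1
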