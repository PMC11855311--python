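# Derivation of the Solpugista composition (ten acrocentric pairs, the two
# largest of roughly double size; 2n = 20) from the hypothetical ancestral
# solifuge karyotype of twelve acrocentric pairs by two tandem fusions of the
# four largest pairs.
start: a=12
sizes: 1.0,0.95,0.90,0.86,0.81,0.77,0.74,0.70,0.66,0.63,0.60,0.57
event: tandem_fusion a+a @ 0,1
event: tandem_fusion a+a @ 0,1
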