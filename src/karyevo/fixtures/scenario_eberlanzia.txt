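# Derivation of the Eberlanzia flava composition (2 biarmed, 2 subtelocentric,
# 7 acrocentric pairs; 2n = 22) from the hypothetical ancestral solifuge
# karyotype of twelve acrocentric pairs: three pericentric inversions followed
# by one centric fusion.
start: a=12
event: pericentric_inversion a->biarmed
event: pericentric_inversion a->st
event: pericentric_inversion a->st
event: centric_fusion a+a
expect: biarmed=2,st=2,a=7
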