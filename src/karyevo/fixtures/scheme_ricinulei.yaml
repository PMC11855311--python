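# Character scheme for Ricinulei (states 0-1; '?' = missing).
order: Ricinulei
characters:
  - id: 1
    name: diploid_number
    kind: diploid_number
    description: "Diploid number"
    states:
      "0": {value: 40}
      "1": {value: 46}
  - id: 2
    name: pair_morphology
    kind: morphology_predominance
    description: "Morphology of chromosome pairs (most biarmed vs most monoarmed)"
    states:
      "0": {label: biarmed_predominant}
      "1": {label: monoarmed_predominant}
  - id: 3
    name: first_pair_size
    kind: first_pair_size
    description: "Relative size of first chromosome pair"
    states:
      "0": {label: gradual}
      "1": {label: first_pair_larger}
  - id: 4
    name: nor_count
    kind: nor_count
    description: "Total number of NOR loci"
    states:
      "0": {value: 1}
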