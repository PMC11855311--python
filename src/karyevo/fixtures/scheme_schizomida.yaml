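# Character scheme for Schizomida (states 0-3; '?' = missing).
order: Schizomida
characters:
  - id: 1
    name: diploid_number
    kind: diploid_number
    description: "Diploid number"
    states:
      "0": {value: 22}
      "1": {value: 20}
      "2": {value: 16}
  - id: 2
    name: pair_morphology
    kind: morphology_predominance
    description: "Morphology of chromosome pairs (all/almost all monoarmed vs mixed)"
    states:
      "0": {label: monoarmed_predominant}
      "1": {label: approximately_same}
  - id: 3
    name: nor_count
    kind: nor_count
    description: "Total number of NOR loci"
    states:
      "0": {value: 1}
  - id: 4
    name: nor_location
    kind: nor_location
    description: "Location of NOR locus on chromosome pair"
    states:
      "0": {label: terminal}
      "1": {label: interstitial}
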