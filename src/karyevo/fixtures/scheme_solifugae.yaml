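# Character scheme for Solifugae (states 0-6; '?' = missing).
order: Solifugae
characters:
  - id: 1
    name: diploid_number
    kind: diploid_number
    description: "Diploid number"
    states:
      "0": {value: 24}
      "1": {value: 22}
      "2": {value: 20}
      "3": {value: 18}
      "4": {value: 16}
      "5": {value: 12}
      "6": {value: 10}
  - id: 2
    name: pair_morphology
    kind: morphology_predominance
    description: "Morphology of chromosome pairs (all/almost all acrocentric vs biarmed predominant)"
    states:
      "0": {label: monoarmed_predominant}
      "1": {label: biarmed_predominant}
  - id: 3
    name: nor_count
    kind: nor_count
    description: "Total number of NOR loci"
    states:
      "0": {value: 1}
      "1": {label: most_pairs_1_2}
  - id: 4
    name: nor_location
    kind: nor_location
    description: "Location of NOR loci on chromosome pairs"
    states:
      "0": {label: terminal}
      "1": {label: subterminal}
  - id: 5
    name: ch_pattern
    kind: ch_pattern
    description: "Pattern of constitutive heterochromatin"
    states:
      "0": {label: low}
      "1": {label: enormous}
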