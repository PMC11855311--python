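# Character scheme for Thelyphonida (states 0-6; '?' = missing).
order: Thelyphonida
characters:
  - id: 1
    name: diploid_number
    kind: diploid_number
    description: "Diploid number"
    states:
      "0": {range: [72, 78]}
      "1": {value: 66}
      "2": {range: [42, 44]}
      "3": {value: 40}
      "4": {value: 38}
      "5": {value: 36}
      "6": {value: 28}
  - id: 2
    name: pair_morphology
    kind: morphology_predominance
    description: "Morphology of chromosome pairs"
    states:
      "0": {label: monoarmed_predominant}
      "1": {label: approximately_same}
      "2": {label: biarmed_predominant}
  - id: 3
    name: sex_differentiation
    kind: sex_differentiation
    description: "Morphological differentiation of putative sex chromosomes X and Y"
    states:
      "0": {label: none_or_homomorphic}
      "1": {label: heteromorphic}
  - id: 4
    name: nor_count
    kind: nor_count
    description: "Total number of NOR loci"
    states:
      "0": {values: [2, 3]}
      "1": {value: 1}
      "2": {value: 5}
  - id: 5
    name: nor_location
    kind: nor_location
    description: "Location of NOR loci on chromosome pairs"
    states:
      "0": {label: terminal}
  - id: 6
    name: ch_pattern
    kind: ch_pattern
    description: "Pattern of constitutive heterochromatin"
    states:
      "0": {label: low}
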