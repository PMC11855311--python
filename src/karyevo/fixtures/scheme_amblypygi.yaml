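# Character scheme for Amblypygi (states 0-9 then A-G; '?' = missing).
order: Amblypygi
characters:
  - id: 1
    name: diploid_number
    kind: diploid_number
    description: "Diploid number"
    states:
      "0": {range: [74, 78]}
      "1": {value: 86}
      "2": {value: 72}
      "3": {value: 70}
      "4": {value: 68}
      "5": {value: 66}
      "6": {value: 64}
      "7": {value: 56}
      "8": {value: 52}
      "9": {value: 50}
      "A": {value: 42}
      "B": {value: 36}
      "C": {value: 34}
      "D": {value: 32}
      "E": {value: 30}
      "F": {value: 24}
      "G": {value: 22}
  - id: 2
    name: pair_morphology
    kind: morphology_predominance
    description: "Morphology of chromosome pairs"
    states:
      "0": {label: monoarmed_predominant}
      "1": {label: approximately_same}
      "2": {label: biarmed_predominant}
  - id: 3
    name: nor_count
    kind: nor_count
    description: "Total number of NOR loci"
    states:
      "0": {value: 1}
      "1": {value: 2}
      "2": {value: 3}
  - id: 4
    name: nor_location
    kind: nor_location
    description: "Location of NOR loci on chromosome pairs"
    states:
      "0": {label: terminal}
      "1": {label: interstitial}
      "2": {label: pericentric}
  - id: 5
    name: sex_linked_nor
    kind: x_linked_nor
    description: "Sex-chromosome linked NORs"
    states:
      "0": {label: autosomal}
      "1": {label: x_linked}
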