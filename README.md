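# karyevo

Comparative cytogenetics of arachnid karyotype evolution, built for the
orders Amblypygi, Thelyphonida, Schizomida (the non-spider tetrapulmonates)
plus Ricinulei and Solifugae — taxa with no genome assemblies, where the
comparative signal lives in karyotype descriptors measured from chromosome
spreads and meiotic plates. The package turns those descriptors into a
tested, reproducible pipeline:

* **Karyotype descriptors** — chromosome morphology from arm ratios
  (Levan-style bins: M 1.0–1.7, SM 1.7–3.0, ST 3.0–7.0, A > 7.0, with
  transitional `a/b` composites near bin edges), relative pair lengths as
  percent of total chromosome length (%TCL), and the biarmed/monoarmed
  predominance call (counts within two pairs of each other are
  "approximately the same"; SM/ST transitional pairs sit out of the
  comparison).
* **Meiotic statistics** — mean chiasma frequency *f* = Σ chiasmata /
  Σ bivalents pooled over late-prophase-I plates, banded as low
  [1.0, 1.2), moderate [1.2, 1.6), relatively high [1.6, 2.5); per-chiasma
  positional classification (pericentric / distal / subdistal /
  interstitial, with intercalar as the unknown-centromere fallback) using
  10%-of-chromosome-length cuts.
* **Character coding** — per-order discrete character schemes (diploid
  number, morphology predominance, NOR count and location, sex-chromosome
  differentiation, heterochromatin pattern) with one-symbol states `0–9`
  then `A–G` and `?` for missing; encoders reproduce the published
  taxon-by-character matrices from the karyotype records.
* **Ancestral karyotypes** — unordered-state (Fitch) parsimony on rooted
  order-level topologies via the Sankoff dynamic programme (polytomies
  native), MPR state sets per node, ACCTRAN/DELTRAN resolutions, and
  unique vs non-unique synapomorphy labelling per branch.
* **Rearrangement scenarios** — an event algebra over karyotype
  compositions (centric fusion, tandem fusion, fission, pericentric
  inversion, polyploidization) with provably minimal event scenarios found
  by breadth-first search over composition space.
* **Synthetic data** — seeded generators for measured spreads, meiotic
  plates and characters evolved on trees with known ancestral truth, so
  every estimator is testable end to end.

## Worked example

Ancestral diploid number of Ricinulei from the packaged matrix and
topology, and a minimal rearrangement scenario:

```python
>>> from karyevo import load_fixture, reconstruct_root_karyotype
>>> tree = load_fixture("ricinulei.tree")          # (Outgroup,(Ricinoides,(Cryptocellus,Pseudocellus)))
>>> matrix = load_fixture("ricinulei.matrix")      # 4 taxa x 4 characters
>>> recon = reconstruct_root_karyotype(tree, matrix)
>>> recon[1]["meanings"], recon[1]["length"]
([40], 1)
>>> from karyevo import KaryotypeComposition, min_scenario
>>> counts, witness = min_scenario(
...     KaryotypeComposition(biarmed=17, a=21),    # 2n=76, 17 biarmed pairs
...     KaryotypeComposition(biarmed=27, a=6),     # 2n=66, 27 biarmed pairs
...     allowed_kinds=("centric_fusion", "pericentric_inversion"))
>>> counts
{'centric_fusion': 5, 'pericentric_inversion': 5}
```

The first result says the most parsimonious ancestral ricinuleid karyotype
had 40 chromosomes (a single state change on the tree, the 46-chromosome
karyotype of *Cryptocellus* being derived). The second says the cheapest
way to turn a 38-pair karyotype with 17 biarmed pairs into a 33-pair one
with 27 biarmed pairs is five centric fusions plus five pericentric
inversions — ten events, no shorter sequence exists.

The numbered scripts under `analysis/` drive the full study: composition
summaries (`01`), matrix encoding with a 57/57 concordance check against
the transcribed matrices (`02`), ancestral reconstructions with
synapomorphy maps (`03`), rearrangement scenarios including the solifuge
tandem-fusion chains and the two-round polyploidization arithmetic (`04`),
and generator parameter-recovery studies (`05`). Each writes its tables
under `results/`. A `karyevo` CLI (`summarize`, `chiasma`, `encode`,
`ancestral`, `scenario`, `simulate`, `run`) exposes the same stages on
user-supplied TSV/Newick files.

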