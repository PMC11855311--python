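#!/usr/bin/env python
"""Minimal rearrangement scenarios between observed karyotype compositions.

Recomputes, by breadth-first search over composition space, the event
counts behind the order-level evolutionary hypotheses: the schizomid
three-fusion reduction, the whip-spider five-fusion/five-inversion
transition, the solifuge tandem-fusion chains and the desert-solifuge
inversion+fusion derivation, plus the two-round polyploidization linking
the schizomid-like ancestor to the high chromosome numbers of the other
tetrapulmonate orders. Writes results/scenarios.tsv.
"""

from pathlib import Path

from karyevo.io import load_fixture
from karyevo.rearrangements import (
    KaryotypeComposition as KC,
    RearrangementEvent as Ev,
    apply_event,
    min_scenario,
    validate_scenario,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = ["scenario\tevents\tend_composition\tend_2n"]

    def row(name, counts, end):
        ev = ", ".join(f"{k} x{v}" for k, v in sorted(counts.items())) or "none"
        rows.append(f"{name}\t{ev}\tbiarmed={end.biarmed},st={end.st},a={end.a}"
                    f"\t{end.diploid_number}")
        print(f"  {name}: {ev} -> 2n={end.diploid_number}")

    print("minimal scenarios (BFS):")
    counts, wit = min_scenario(KC(a=11), lambda c: c.n_pairs == 8,
                               allowed_kinds=("centric_fusion",))
    row("schizomid 11 monoarmed pairs -> 8 pairs", counts, wit.end)

    counts, wit = min_scenario(
        KC(biarmed=17, a=21), KC(biarmed=27, a=6),
        allowed_kinds=("centric_fusion", "pericentric_inversion"))
    row("whip spider 2n=76 (17 biarmed) -> 2n=66 (27 biarmed)", counts, wit.end)

    counts, wit = min_scenario(
        KC(a=12), KC(biarmed=2, st=2, a=7),
        allowed_kinds=("centric_fusion", "pericentric_inversion"),
        coarse_inversions=False)
    row("ancestral solifuge -> desert daesiid (2n=22)", counts, wit.end)

    print("replayed event chains (packaged scenario files):")
    for name in ("eberlanzia", "solpugista", "gluvia"):
        start, events, expect = load_fixture(f"{name}.scenario")
        end, rep = validate_scenario(start, events, expected=expect,
                                     size_aware=start.sizes is not None)
        row(f"fixture chain: {name}", rep["event_counts"], end)
        if rep["matches_expected"] is False:
            raise SystemExit(f"{name}: replay does not reach the expected composition")

    print("polyploidization chain:")
    comp = KC(a=11)
    for k in range(1, 3):
        comp = apply_event(comp, Ev("polyploidization"))
        row(f"schizomid-like 2n=22 after {k} genome doubling(s)",
            {"polyploidization": k}, comp)

    (OUT / "scenarios.tsv").write_text("\n".join(rows) + "\n")
    print(f"wrote {OUT / 'scenarios.tsv'}")


if __name__ == "__main__":
    main()
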