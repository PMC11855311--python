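"""Rearrangement event algebra and minimal-scenario search vs an oracle."""

import random
from collections import deque

import pytest

from karyevo.rearrangements import (
    KaryotypeComposition as KC,
    RearrangementEvent as Ev,
    apply_event,
    min_scenario,
    validate_scenario,
)


# --- independent oracle: plain BFS with its own inline transition rules -----

def oracle_distance(src_key, tgt_key, kinds, max_pairs=40):
    """Shortest event count between count vectors (biarmed, st, a)."""
    def neighbours(key):
        bi, st, a = key
        out = set()
        if "centric_fusion" in kinds:
            for d_st, d_a in ((2, 0), (1, 1), (0, 2)):
                if st >= d_st and a >= d_a:
                    out.add((bi + 1, st - d_st, a - d_a))
        if "tandem_fusion" in kinds and a >= 2:
            out.add((bi, st, a - 1))
        if "fission" in kinds and bi >= 1:
            for d_st, d_a in ((2, 0), (1, 1), (0, 2)):
                out.add((bi - 1, st + d_st, a + d_a))
        if "pericentric_inversion" in kinds:
            # fine-grained shifts: a <-> st <-> biarmed and a <-> biarmed
            if a >= 1:
                out.add((bi + 1, st, a - 1))
                out.add((bi, st + 1, a - 1))
            if st >= 1:
                out.add((bi + 1, st - 1, a))
                out.add((bi, st - 1, a + 1))
            if bi >= 1:
                out.add((bi - 1, st + 1, a))
                out.add((bi - 1, st, a + 1))
        if "polyploidization" in kinds:
            out.add((2 * bi, 2 * st, 2 * a))
        return {k for k in out if sum(k) <= max_pairs}

    if src_key == tgt_key:
        return 0
    seen = {src_key}
    frontier = deque([(src_key, 0)])
    while frontier:
        key, d = frontier.popleft()
        for nxt in neighbours(key):
            if nxt in seen:
                continue
            if nxt == tgt_key:
                return d + 1
            seen.add(nxt)
            frontier.append((nxt, d + 1))
    return None


class TestApplyEvent:
    def test_centric_fusion(self):
        out = apply_event(KC(a=11), Ev("centric_fusion", ("a", "a")))
        assert (out.biarmed, out.a, out.n_pairs, out.diploid_number) == (1, 9, 10, 20)

    def test_polyploidization_doubles(self):
        out = apply_event(KC(a=11), Ev("polyploidization"))
        assert out.a == 22 and out.diploid_number == 44

    def test_fission_inverse_of_fusion_on_counts(self):
        start = KC(biarmed=3, st=1, a=4)
        fused = apply_event(start, Ev("centric_fusion", ("st", "a")))
        back = apply_event(fused, Ev("fission", ("st", "a")))
        assert back.counts_key() == start.counts_key()

    def test_inversion_preserves_pair_count(self):
        out = apply_event(KC(biarmed=2, a=3), Ev("pericentric_inversion", ("a", "biarmed")))
        assert out.n_pairs == 5 and out.biarmed == 3 and out.a == 2

    def test_insufficient_operands(self):
        with pytest.raises(ValueError):
            apply_event(KC(a=1), Ev("centric_fusion", ("a", "a")))

    def test_size_conservation_under_fusion(self):
        comp = KC(a=4, sizes=(4.0, 3.0, 2.0, 1.0))
        out = apply_event(comp, Ev("tandem_fusion", ("a", "a"), size_operands=(0, 1)))
        assert sum(out.sizes) == pytest.approx(sum(comp.sizes))
        assert sorted(out.sizes) == pytest.approx([1.0, 2.0, 7.0])

    def test_polyploidization_doubles_material(self):
        comp = KC(a=2, sizes=(2.0, 1.0))
        out = apply_event(comp, Ev("polyploidization"))
        assert sum(out.sizes) == pytest.approx(2 * sum(comp.sizes))


class TestMinScenario:
    def test_three_fusions_from_eleven_to_eight_pairs(self):
        counts, witness = min_scenario(
            KC(a=11), lambda c: c.n_pairs == 8, allowed_kinds=("centric_fusion",)
        )
        assert counts == {"centric_fusion": 3}
        assert witness.end.n_pairs == 8

    def test_identity(self):
        counts, witness = min_scenario(KC(a=5), KC(a=5))
        assert counts == {} and witness.events == []

    def test_five_fusions_five_inversions(self):
        counts, _ = min_scenario(
            KC(biarmed=17, a=21), KC(biarmed=27, a=6),
            allowed_kinds=("centric_fusion", "pericentric_inversion"),
        )
        assert counts == {"centric_fusion": 5, "pericentric_inversion": 5}

    def test_unreachable_reported(self):
        assert min_scenario(KC(a=4), KC(a=5), allowed_kinds=("centric_fusion",)) is None

    def test_matches_oracle_on_random_instances(self):
        rng = random.Random(424242)
        kind_pool = ["centric_fusion", "tandem_fusion", "fission",
                     "pericentric_inversion", "polyploidization"]
        for case in range(200):
            src = KC(biarmed=rng.randint(0, 4), st=rng.randint(0, 4),
                     a=rng.randint(0, 4))
            if src.n_pairs == 0 or src.n_pairs > 12:
                continue
            tgt = KC(biarmed=rng.randint(0, 4), st=rng.randint(0, 4),
                     a=rng.randint(0, 4))
            if tgt.n_pairs == 0:
                continue
            kinds = tuple(rng.sample(kind_pool, rng.randint(1, 5)))
            expected = oracle_distance(src.counts_key(), tgt.counts_key(), kinds)
            got = min_scenario(src, tgt, allowed_kinds=kinds,
                               coarse_inversions=False, max_pairs=40)
            if expected is None:
                assert got is None, f"case {case}"
            else:
                assert got is not None and len(got[1].events) == expected, (
                    f"case {case}: {src} -> {tgt} via {kinds}"
                )

    def test_symmetry_for_reversible_event_sets(self):
        rng = random.Random(11)
        kinds = ("centric_fusion", "fission", "pericentric_inversion")
        for _ in range(30):
            a = KC(biarmed=rng.randint(0, 4), st=rng.randint(0, 3), a=rng.randint(1, 4))
            b = KC(biarmed=rng.randint(0, 4), st=rng.randint(0, 3), a=rng.randint(1, 4))
            d_ab = min_scenario(a, b, allowed_kinds=kinds, coarse_inversions=False)
            d_ba = min_scenario(b, a, allowed_kinds=kinds, coarse_inversions=False)
            assert (d_ab is None) == (d_ba is None)
            if d_ab:
                assert len(d_ab[1].events) == len(d_ba[1].events)

    def test_triangle_inequality(self):
        rng = random.Random(13)
        kinds = ("centric_fusion", "fission", "pericentric_inversion")
        for _ in range(20):
            comps = [
                KC(biarmed=rng.randint(0, 3), st=rng.randint(0, 3), a=rng.randint(1, 4))
                for _ in range(3)
            ]
            d = {}
            for i, j in ((0, 1), (1, 2), (0, 2)):
                res = min_scenario(comps[i], comps[j], allowed_kinds=kinds,
                                   coarse_inversions=False)
                d[(i, j)] = None if res is None else len(res[1].events)
            if None not in d.values():
                assert d[(0, 2)] <= d[(0, 1)] + d[(1, 2)]

    def test_witness_replays_to_target(self):
        counts, witness = min_scenario(
            KC(a=12), KC(biarmed=2, st=2, a=7),
            allowed_kinds=("centric_fusion", "pericentric_inversion"),
            coarse_inversions=False,
        )
        assert witness.end.counts_key() == (2, 2, 7)
        assert counts == {"centric_fusion": 1, "pericentric_inversion": 3}


class TestValidateScenario:
    def test_desert_solifuge_derivation(self):
        """Twelve acrocentric pairs -> three inversions + one fusion gives
        the 2 biarmed / 2 subtelocentric / 7 acrocentric, 2n=22 pattern."""
        events = [
            Ev("pericentric_inversion", ("a", "biarmed")),
            Ev("pericentric_inversion", ("a", "st")),
            Ev("pericentric_inversion", ("a", "st")),
            Ev("centric_fusion", ("a", "a")),
        ]
        end, report = validate_scenario(KC(a=12), events, expected=KC(biarmed=2, st=2, a=7))
        assert end.diploid_number == 22
        assert report["matches_expected"] is True

    def test_tandem_fusion_chain_with_sizes(self):
        """Twelve equal acrocentrics -> two tandem fusions leave ten pairs,
        two of double relative size."""
        comp = KC(a=12, sizes=(1.0,) * 12)
        events = [Ev("tandem_fusion", ("a", "a"), size_operands=(0, 1))] * 2
        end, _ = validate_scenario(comp, events)
        assert end.n_pairs == 10
        assert sorted(end.sizes, reverse=True)[:2] == [2.0, 2.0]

    def test_second_tandem_round_reaches_five_pairs(self):
        comp = KC(a=10, sizes=(2.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0))
        events = [Ev("tandem_fusion", ("a", "a"), size_operands=(0, 1))] * 5
        end, _ = validate_scenario(comp, events)
        assert end.n_pairs == 5 and end.diploid_number == 10

    def test_error_names_failing_step(self):
        events = [Ev("centric_fusion", ("a", "a"))] * 3
        with pytest.raises(ValueError, match="event 3"):
            validate_scenario(KC(a=4), events)

    def test_packaged_scenarios_replay(self):
        from karyevo.io import load_fixture
        for name, expected_end in (
            ("eberlanzia", (2, 2, 7)),
            ("solpugista", (0, 0, 10)),
            ("gluvia", (0, 0, 5)),
        ):
            start, events, expect = load_fixture(f"{name}.scenario")
            end, report = validate_scenario(start, events, expected=expect)
            assert end.counts_key() == expected_end
            if expect is not None:
                assert report["matches_expected"] is True
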