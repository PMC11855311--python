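"""Synthetic-data generators: determinism, validity, parameter recovery."""

import pytest

from karyevo.karyotype import MorphologyClass as MC, classify_morphology
from karyevo.meiosis import classify_chiasma_position, mean_chiasma_frequency
from karyevo.parsimony import RootedTree, fitch
from karyevo.simulate import (
    CharEvolSimConfig,
    MeiosisSimConfig,
    SpreadSimConfig,
    simulate_characters,
    simulate_meiosis,
    simulate_spread,
)

TEN_TIP_TREE = "((t0,(t1,t2)),((t3,t4),((t5,t6),(t7,(t8,t9)))));"


class TestSpreadSimulator:
    def test_deterministic_given_seed(self):
        cfg = SpreadSimConfig(composition={MC.M: 5, MC.A: 5}, noise_sd=0.05, seed=42)
        assert simulate_spread(cfg) == simulate_spread(cfg)

    def test_different_seed_differs(self):
        a = simulate_spread(SpreadSimConfig(composition={MC.M: 5}, noise_sd=0.05, seed=1))
        b = simulate_spread(SpreadSimConfig(composition={MC.M: 5}, noise_sd=0.05, seed=2))
        assert a != b

    def test_zero_noise_perfect_recovery(self):
        cfg = SpreadSimConfig(
            composition={MC.M: 20, MC.SM: 20, MC.ST: 20, MC.A: 20}, noise_sd=0.0, seed=3
        )
        chroms, truth = simulate_spread(cfg)
        got = [classify_morphology(c.short_arm, c.long_arm) for c in chroms]
        assert got == truth

    def test_noisy_recovery_rate(self):
        # 5% relative measurement noise: at least 95% of 1000 chromosomes
        # still classify into their true bin
        cfg = SpreadSimConfig(
            composition={MC.M: 250, MC.SM: 250, MC.ST: 250, MC.A: 250},
            noise_sd=0.05,
            seed=4,
        )
        chroms, truth = simulate_spread(cfg)
        got = [classify_morphology(c.short_arm, c.long_arm) for c in chroms]
        rate = sum(g is t for g, t in zip(got, truth)) / len(truth)
        assert rate >= 0.95

    def test_impossible_config_rejected(self):
        with pytest.raises(ValueError):
            SpreadSimConfig(composition={MC.M_SM: 3})
        with pytest.raises(ValueError):
            SpreadSimConfig(composition={MC.M: 3}, noise_sd=-0.1)


class TestMeiosisSimulator:
    def test_deterministic_given_seed(self):
        cfg = MeiosisSimConfig(seed=5)
        assert simulate_meiosis(cfg) == simulate_meiosis(cfg)

    def test_single_chiasma_gives_unit_frequency(self):
        cfg = MeiosisSimConfig(chiasma_count_probs={1: 1.0}, seed=6)
        assert mean_chiasma_frequency(simulate_meiosis(cfg)) == 1.0

    def test_law_of_large_numbers(self):
        # 10^4 bivalents at true rate 1.2 -> estimate within 0.02
        cfg = MeiosisSimConfig(
            n_plates=100, bivalents_per_plate=100,
            chiasma_count_probs={1: 0.8, 2: 0.2}, seed=7,
        )
        plates = simulate_meiosis(cfg)
        f = mean_chiasma_frequency(plates)
        assert abs(f - cfg.true_frequency) <= 0.02

    def test_position_category_recovery(self):
        # classified proportions match the simulated mixture within 0.02
        mixture = {"pericentric": 0.3, "distal": 0.3, "interstitial": 0.4}
        cfg = MeiosisSimConfig(
            n_plates=100, bivalents_per_plate=100,
            chiasma_count_probs={1: 1.0}, position_mixture=mixture, seed=8,
        )
        plates = simulate_meiosis(cfg)
        counts = {"pericentric": 0, "distal": 0, "interstitial": 0}
        total = 0
        for plate in plates:
            for biv in plate.bivalents:
                for i in range(biv.n_chiasmata):
                    cat = classify_chiasma_position(biv, i, refine_subdistal=False)
                    counts[cat] += 1
                    total += 1
        for cat, p in mixture.items():
            assert abs(counts[cat] / total - p) <= 0.02, cat

    def test_generated_plates_pass_validators(self):
        for plate in simulate_meiosis(MeiosisSimConfig(seed=9)):
            assert plate.validate() == []

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            MeiosisSimConfig(chiasma_count_probs={1: 0.5, 2: 0.4})
        with pytest.raises(ValueError):
            MeiosisSimConfig(chiasma_count_probs={0: 0.5, 1: 0.5})


class TestCharacterSimulator:
    def tree(self):
        return RootedTree.from_newick(TEN_TIP_TREE)

    def test_deterministic_given_seed(self):
        cfg = CharEvolSimConfig(tree=self.tree(), states=("0", "1", "2"),
                                expected_changes=1.0, seed=10)
        assert simulate_characters(cfg)[0] == simulate_characters(cfg)[0]

    def test_zero_changes_all_tips_equal_root(self):
        cfg = CharEvolSimConfig(tree=self.tree(), states=("0", "1"),
                                expected_changes=0.0, seed=11)
        tips, truth = simulate_characters(cfg)
        assert set(tips.values()) == {"0"}
        res = fitch(self.tree(), tips, state_space=("0", "1"))
        assert res.length == 0

    def test_root_state_recovery_rate(self):
        """With at most one expected change per character, Fitch recovers
        the true root state in at least 95% of 500 replicates."""
        tree = self.tree()
        hits = 0
        for rep in range(500):
            cfg = CharEvolSimConfig(tree=tree, states=("0", "1", "2"),
                                    expected_changes=1.0, root_state="0",
                                    seed=1000 + rep)
            tips, truth = simulate_characters(cfg)
            if len(set(tips.values())) == 0:
                continue
            res = fitch(tree, tips, state_space=("0", "1", "2"))
            hits += "0" in res.root_set
        assert hits / 500 >= 0.95

    def test_tiny_tree_rejected(self):
        tree = RootedTree.from_newick("(a,b);")
        with pytest.raises(ValueError):
            CharEvolSimConfig(tree=tree, states=("0", "1"))
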