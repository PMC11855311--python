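"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, each a pure function of its config (seed included), each
with its own pseudo-random stream so adding one generator never shifts
another's draws:

* measured chromosome spreads — arm lengths drawn inside a target
  morphology class's arm-ratio bin, perturbed by relative measurement
  noise, with the true class recorded per chromosome;
* meiotic plates — per-bivalent chiasma counts from a small categorical
  distribution and chiasma positions from a pericentric/distal/
  interstitial mixture that mirrors the positional classifier, so category
  recovery is well-posed;
* character evolution on a tree — a fixed expected number of unit changes
  scattered over branches by a Poisson process, with every true node state
  recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from .karyotype import DEFAULT_BINS, MeasuredChromosome, MorphologyClass
from .meiosis import BivalentObservation, MeioticPlate
from .parsimony import RootedTree, TreeNode

__all__ = [
    "SpreadSimConfig",
    "MeiosisSimConfig",
    "CharEvolSimConfig",
    "simulate_spread",
    "simulate_meiosis",
    "simulate_characters",
]

_PURE_BINS = {
    MorphologyClass.M: (1.0, DEFAULT_BINS[0][1]),
    MorphologyClass.SM: (DEFAULT_BINS[0][1], DEFAULT_BINS[1][1]),
    MorphologyClass.ST: (DEFAULT_BINS[1][1], DEFAULT_BINS[2][1]),
    MorphologyClass.A: (DEFAULT_BINS[2][1], math.inf),
}
_A_RATIO_CAP = 12.0  # practical upper arm ratio for sampling acrocentrics


@dataclass(frozen=True)
class SpreadSimConfig:
    """True composition and measurement model for one simulated spread."""

    composition: Mapping[MorphologyClass, int]
    noise_sd: float = 0.0              # relative SD on each arm length
    size_decrease: float = 0.95        # geometric factor, largest pair = 1
    sizes: tuple[float, ...] | None = None  # explicit total lengths, overrides
    edge_margin: float = 0.15          # keep ratios off bin edges (relative)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.composition or any(v < 0 for v in self.composition.values()):
            raise ValueError("composition must be non-empty with counts >= 0")
        for cls in self.composition:
            if cls not in _PURE_BINS:
                raise ValueError(f"cannot target composite/unknown class {cls}")


def simulate_spread(
    cfg: SpreadSimConfig,
) -> tuple[list[MeasuredChromosome], list[MorphologyClass]]:
    """Draw measured chromosomes plus their ground-truth classes.

    Arm ratios are uniform inside the target class's bin shrunk by
    ``edge_margin`` at each edge (so the noiseless classification with the
    default boundary tolerance returns the pure class), then both arms are
    multiplied by independent relative Gaussian noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC0FFEE]))
    truth: list[MorphologyClass] = []
    for cls, count in cfg.composition.items():
        truth.extend([cls] * count)
    n = len(truth)
    if cfg.sizes is not None:
        if len(cfg.sizes) != n:
            raise ValueError("sizes length must equal chromosome count")
        totals = list(cfg.sizes)
    else:
        totals = [10.0 * cfg.size_decrease**i for i in range(n)]

    chroms: list[MeasuredChromosome] = []
    for cls, total in zip(truth, totals):
        lo, hi = _PURE_BINS[cls]
        hi = min(hi, _A_RATIO_CAP)
        margin = cfg.edge_margin
        lo_eff = lo * (1 + margin) if lo > 1.0 else lo
        hi_eff = hi * (1 - margin) if math.isfinite(hi) else hi
        r = rng.uniform(lo_eff, hi_eff)
        short = total / (1 + r)
        long = total - short
        if cfg.noise_sd > 0:
            short *= max(1e-6, 1 + rng.normal(0, cfg.noise_sd))
            long *= max(1e-6, 1 + rng.normal(0, cfg.noise_sd))
        if short > long:
            short, long = long, short
        chroms.append(MeasuredChromosome(short_arm=short, long_arm=long))
    return chroms, truth


@dataclass(frozen=True)
class MeiosisSimConfig:
    n_plates: int = 10
    bivalents_per_plate: int = 10
    chiasma_count_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.8, 2: 0.2}
    )
    position_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"pericentric": 0.2, "distal": 0.4, "interstitial": 0.4}
    )
    chromosome_length: float = 100.0
    centromere_fraction: float = 0.3   # centromere position as fraction of length
    threshold: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for probs, name in ((self.chiasma_count_probs, "chiasma_count_probs"),
                            (self.position_mixture, "position_mixture")):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if any(k < 1 for k in self.chiasma_count_probs):
            raise ValueError("bivalents carry at least one chiasma")
        c = self.centromere_fraction
        if not (self.threshold < c < 1 - self.threshold):
            raise ValueError("centromere must leave both arms longer than the cut")

    @property
    def true_frequency(self) -> float:
        return sum(k * p for k, p in self.chiasma_count_probs.items())


def _draw_position(rng: np.random.Generator, cat: str, cfg: MeiosisSimConfig) -> float:
    """One chiasma position consistent with the classifier's category."""
    L = cfg.chromosome_length
    c = cfg.centromere_fraction * L
    cut = cfg.threshold * L
    eps = 1e-9 * L
    if cat == "pericentric":
        lo, hi = max(0.0, c - cut + eps), min(L, c + cut - eps)
        return rng.uniform(lo, hi)
    if cat == "distal":
        if rng.random() < c / L:  # pick an arm weighted by its length
            return rng.uniform(0.0, cut - eps)
        return rng.uniform(L - cut + eps, L)
    if cat == "interstitial":
        # the two interstitial spans, away from both cuts
        spans = [(cut + eps, c - cut - eps), (c + cut + eps, L - cut - eps)]
        spans = [(a, b) for a, b in spans if b > a]
        weights = np.array([b - a for a, b in spans])
        a, b = spans[rng.choice(len(spans), p=weights / weights.sum())]
        return rng.uniform(a, b)
    raise ValueError(f"unknown position category {cat!r}")


def simulate_meiosis(cfg: MeiosisSimConfig) -> list[MeioticPlate]:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED5]))
    counts = sorted(cfg.chiasma_count_probs)
    count_p = np.array([cfg.chiasma_count_probs[k] for k in counts])
    cats = sorted(cfg.position_mixture)
    cat_p = np.array([cfg.position_mixture[k] for k in cats])
    plates: list[MeioticPlate] = []
    for i in range(cfg.n_plates):
        bivalents = []
        for _ in range(cfg.bivalents_per_plate):
            k = counts[rng.choice(len(counts), p=count_p)]
            positions = tuple(
                _draw_position(rng, cats[rng.choice(len(cats), p=cat_p)], cfg)
                for _ in range(k)
            )
            bivalents.append(
                BivalentObservation(
                    chromosome_length=cfg.chromosome_length,
                    centromere_position=cfg.centromere_fraction * cfg.chromosome_length,
                    chiasma_positions=positions,
                )
            )
        plates.append(MeioticPlate(plate_id=f"sim{i:03d}", bivalents=tuple(bivalents)))
    return plates


@dataclass(frozen=True)
class CharEvolSimConfig:
    tree: RootedTree
    states: tuple[Hashable, ...]
    expected_changes: float = 1.0
    root_state: Hashable | None = None  # default: first state
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expected_changes < 0:
            raise ValueError("expected_changes must be >= 0")
        if len(self.states) < 2:
            raise ValueError("need at least two states")
        if self.tree.n_tips() < 3:
            raise ValueError("tree needs at least three tips")


def simulate_characters(
    cfg: CharEvolSimConfig,
) -> tuple[dict[str, Hashable], dict[int, Hashable]]:
    """Evolve one character down the tree with a known ancestral truth.

    Each branch receives a Poisson(expected_changes / n_branches) number
    of changes; each change replaces the current state by a uniform draw
    from the other states. Returns (tip states by label, true state per
    node keyed by id(node)).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xCAB1E]))
    root_state = cfg.root_state if cfg.root_state is not None else cfg.states[0]
    if root_state not in cfg.states:
        raise ValueError("root_state outside the state space")
    branches = sum(1 for n in cfg.tree.root.preorder()) - 1
    rate = cfg.expected_changes / branches if branches else 0.0

    truth: dict[int, Hashable] = {id(cfg.tree.root): root_state}
    tips: dict[str, Hashable] = {}
    others = {s: [t for t in cfg.states if t != s] for s in cfg.states}
    for node in cfg.tree.root.preorder():
        state = truth[id(node)]
        if node.is_leaf and node is not cfg.tree.root:
            tips[node.label] = state
        for child in node.children:
            s = state
            for _ in range(rng.poisson(rate)):
                s = others[s][rng.integers(len(others[s]))]
            truth[id(child)] = s
            if child.is_leaf:
                tips[child.label] = s
    return tips, truth
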