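"""Chiasma frequency and position statistics from late-prophase-I plates.

The mean chiasma frequency f is the pooled ratio: total chiasmata over
total bivalents across all scored plates (diplotene-diakinesis). It is
classified into the conventional bands low [1.0, 1.2), moderate [1.2, 1.6)
and relatively high [1.6, 2.5); the printed band edges (1.19/1.2, 1.59/1.6)
are decimal truncations of these half-open intervals.

Chiasma positions are classified against the whole-chromosome length L of
one chromosome of the bivalent:

  pericentric   chiasma-centromere distance < 10% of L, or the chiasma sits
                on an arm that is itself <= 10% of L (then every chiasma of
                that arm is pericentric);
  distal        distance from the telomeric end of its arm < 10% of L;
  interstitial  the rest of the arm, with the refinement "subdistal" for
                the distal 20% of the arm's interstitial span;
  intercalar    fallback when the centromere is unknown: anything more than
                10% of L from both bivalent ends (closer than that is
                distal).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "BivalentObservation",
    "MeioticPlate",
    "ChiasmaSummary",
    "POSITION_CATEGORIES",
    "mean_chiasma_frequency",
    "classify_frequency",
    "classify_chiasma_position",
    "position_spectrum",
]

POSITION_CATEGORIES = ("pericentric", "distal", "subdistal", "interstitial", "intercalar")

FREQUENCY_BINS = (
    ("low", 1.0, 1.2),
    ("moderate", 1.2, 1.6),
    ("relatively_high", 1.6, 2.5),
)


@dataclass(frozen=True)
class BivalentObservation:
    """One bivalent: its measurement frame is one chromosome of the pair."""

    chromosome_length: float
    centromere_position: float | None  # distance from chromosome start; None if unknown
    chiasma_positions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        if self.centromere_position is not None and not (
            0 <= self.centromere_position <= self.chromosome_length
        ):
            raise ValueError("centromere outside chromosome")
        for p in self.chiasma_positions:
            if not (0 <= p <= self.chromosome_length):
                raise ValueError(f"chiasma position {p} outside chromosome")

    @property
    def n_chiasmata(self) -> int:
        return len(self.chiasma_positions)


@dataclass(frozen=True)
class MeioticPlate:
    plate_id: str
    bivalents: tuple[BivalentObservation, ...]

    def __post_init__(self) -> None:
        if not self.bivalents:
            raise ValueError(f"plate {self.plate_id!r} has no bivalents")

    def validate(self) -> list[str]:
        """Bivalents are chiasmate by definition; flag achiasmate entries."""
        return [
            f"plate {self.plate_id}: bivalent {i} carries no chiasma"
            for i, b in enumerate(self.bivalents)
            if b.n_chiasmata == 0
        ]


@dataclass(frozen=True)
class ChiasmaSummary:
    f: float
    n_plates: int
    category: str
    position_counts: dict[str, int] = field(default_factory=dict)


def mean_chiasma_frequency(plates: Sequence[MeioticPlate]) -> float:
    """Pooled mean chiasma frequency: sum chiasmata / sum bivalents."""
    if not plates:
        raise ValueError("no plates supplied")
    n_biv = sum(len(p.bivalents) for p in plates)
    n_chi = sum(b.n_chiasmata for p in plates for b in p.bivalents)
    if n_biv == 0:
        raise ValueError("zero bivalents: frequency undefined")
    return n_chi / n_biv


def classify_frequency(f: float) -> str:
    if f < 0:
        raise ValueError("chiasma frequency cannot be negative")
    if f < 1.0:
        return "out_of_range_low"
    for name, lo, hi in FREQUENCY_BINS:
        if lo <= f < hi:
            return name
    return "out_of_range_high"


def classify_chiasma_position(
    bivalent: BivalentObservation,
    chiasma_index: int,
    threshold: float = 0.10,
    subdistal_fraction: float = 0.20,
    refine_subdistal: bool = True,
) -> str:
    """Classify one chiasma of a bivalent into a positional category.

    ``threshold`` is the pericentric/distal cut as a fraction of the whole
    chromosome length; ``subdistal_fraction`` is the portion of an arm's
    interstitial span nearest the telomere that is reported as subdistal.
    With an unknown centromere only distal vs intercalar can be told apart.
    """
    L = bivalent.chromosome_length
    p = bivalent.chiasma_positions[chiasma_index]
    cut = threshold * L
    c = bivalent.centromere_position
    if c is None:
        return "distal" if min(p, L - p) < cut else "intercalar"
    # which arm carries the chiasma; ties at the centromere go to the longer arm
    on_first_arm = p < c or (p == c and c >= L - c)
    arm_len = c if on_first_arm else L - c
    if arm_len <= cut:
        return "pericentric"
    if abs(p - c) < cut:
        return "pericentric"
    dist_from_end = p if on_first_arm else L - p
    if dist_from_end < cut:
        return "distal"
    if refine_subdistal:
        # interstitial span of this arm: between the distal and pericentric cuts
        span = arm_len - 2 * cut
        if span > 0 and dist_from_end - cut <= subdistal_fraction * span:
            return "subdistal"
    return "interstitial"


def position_spectrum(
    plates: Sequence[MeioticPlate],
    threshold: float = 0.10,
    refine_subdistal: bool = True,
) -> tuple[dict[str, int], dict[str, float]]:
    """Pooled position counts plus the per-plate maximum proportion.

    Returns ``(counts, max_proportion)`` where ``max_proportion[cat]`` is
    the largest share (in percent) that category reached on any single
    plate -- the "up to X% of the chiasmata on a plate" statistic.
    Subdistal is tallied separately but is a refinement of interstitial;
    merge the two for coarse totals.
    """
    pooled: Counter[str] = Counter({c: 0 for c in POSITION_CATEGORIES})
    max_prop: dict[str, float] = {c: 0.0 for c in POSITION_CATEGORIES}
    for plate in plates:
        plate_counts: Counter[str] = Counter()
        for biv in plate.bivalents:
            for i in range(biv.n_chiasmata):
                cat = classify_chiasma_position(
                    biv, i, threshold=threshold, refine_subdistal=refine_subdistal
                )
                plate_counts[cat] += 1
        total = sum(plate_counts.values())
        pooled.update(plate_counts)
        if total:
            for cat, n in plate_counts.items():
                max_prop[cat] = max(max_prop[cat], 100.0 * n / total)
    return dict(pooled), max_prop


def summarize(plates: Sequence[MeioticPlate]) -> ChiasmaSummary:
    f = mean_chiasma_frequency(plates)
    counts, _ = position_spectrum(plates)
    return ChiasmaSummary(
        f=f, n_plates=len(plates), category=classify_frequency(f), position_counts=counts
    )
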