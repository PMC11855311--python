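"""Karyotype representation and per-karyotype descriptors.

A karyotype is described at the resolution cytogenetics works at for taxa
without genome assemblies: the diploid number (2n), and for each chromosome
pair a centromere-position morphology class, a relative length (percent of
the total chromosome length of the diploid set, %TCL) and optional
annotations (NOR loci, heteromorphism).

Morphology classes follow the Levan arm-ratio convention, with the long arm
in the numerator:

    r = long / short
    M  (metacentric)      1.0 <= r < 1.7
    SM (submetacentric)   1.7 <= r < 3.0
    ST (subtelocentric)   3.0 <= r < 7.0
    A  (acrocentric)      r >= 7.0 (or no visible short arm)

Pairs whose ratio falls close to a bin edge are reported as transitional
composites ("M/SM", "SM/ST", "ST/A"), mirroring how karyograms are scored
when the centromere position is equivocal.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_BINS",
    "MorphologyClass",
    "MeasuredChromosome",
    "NorLocus",
    "KaryotypePair",
    "KaryotypeRecord",
    "CompositionSummary",
    "classify_morphology",
    "relative_pair_lengths",
    "composition_summary",
    "parse_pair_list",
]


class MorphologyClass(str, Enum):
    """Centromere-position class of a chromosome pair."""

    M = "M"
    SM = "SM"
    ST = "ST"
    A = "A"
    M_SM = "M/SM"
    SM_ST = "SM/ST"
    ST_A = "ST/A"
    BIARMED = "BIARMED"      # two-armed, finer class unresolved
    MONOARMED = "MONOARMED"  # one-armed, finer class unresolved
    UNKNOWN = "UNKNOWN"

    @property
    def is_composite(self) -> bool:
        return self in (MorphologyClass.M_SM, MorphologyClass.SM_ST, MorphologyClass.ST_A)


# Biarmed = metacentric or submetacentric; monoarmed = subtelocentric or
# acrocentric. M/SM composites are unambiguously biarmed and ST/A composites
# unambiguously monoarmed; only the SM/ST composite straddles the divide and
# is excluded from predominance comparisons.
_BIARMED = {MorphologyClass.M, MorphologyClass.SM, MorphologyClass.M_SM, MorphologyClass.BIARMED}
_MONOARMED = {MorphologyClass.ST, MorphologyClass.A, MorphologyClass.ST_A, MorphologyClass.MONOARMED}

# (class, upper edge of its arm-ratio bin); the last bin is open above.
DEFAULT_BINS: tuple[tuple[MorphologyClass, float], ...] = (
    (MorphologyClass.M, 1.7),
    (MorphologyClass.SM, 3.0),
    (MorphologyClass.ST, 7.0),
    (MorphologyClass.A, math.inf),
)

_COMPOSITE = {
    (MorphologyClass.M, MorphologyClass.SM): MorphologyClass.M_SM,
    (MorphologyClass.SM, MorphologyClass.ST): MorphologyClass.SM_ST,
    (MorphologyClass.ST, MorphologyClass.A): MorphologyClass.ST_A,
}


@dataclass(frozen=True)
class MeasuredChromosome:
    """Arm lengths of one measured chromosome, long arm >= short arm."""

    short_arm: float
    long_arm: float

    def __post_init__(self) -> None:
        if self.long_arm <= 0:
            raise ValueError(f"long arm must be positive, got {self.long_arm}")
        if self.short_arm < 0:
            raise ValueError(f"short arm must be non-negative, got {self.short_arm}")
        if self.short_arm > self.long_arm:
            raise ValueError(
                f"arms must be oriented long >= short, got ({self.short_arm}, {self.long_arm})"
            )

    @property
    def total(self) -> float:
        return self.short_arm + self.long_arm

    @property
    def arm_ratio(self) -> float:
        return math.inf if self.short_arm == 0 else self.long_arm / self.short_arm


@dataclass(frozen=True)
class NorLocus:
    """One NOR locus: which arm it sits on and where along the arm."""

    arm: str = "unknown"        # short | long | unknown
    position: str = "terminal"  # terminal | subterminal | interstitial | pericentric | whole_arm


@dataclass
class KaryotypePair:
    index: int
    morphology: MorphologyClass = MorphologyClass.UNKNOWN
    rel_length: float | None = None
    nor_loci: list[NorLocus] = field(default_factory=list)
    heteromorphic: bool = False
    sex_pair: bool = False

    def __post_init__(self) -> None:
        if self.rel_length is not None and not (0 < self.rel_length <= 100):
            raise ValueError(f"rel_length must lie in (0, 100], got {self.rel_length}")


@dataclass
class KaryotypeRecord:
    """One species' karyotype as assembled from measured spreads."""

    taxon: str
    order: str
    diploid_number: int | None
    pairs: list[KaryotypePair] = field(default_factory=list)
    diploid_number_max: int | None = None  # upper end when sources give a range
    sex_scored: str = "unknown"
    sex_system: str = "unknown"  # none_detected | XY_homomorphic | XY_heteromorphic | unknown
    telomere_motif: str = "unknown"
    ch_pattern: str = "unknown"  # low_centromeric_telomeric | enormous_blocks | unknown
    nor_locus_count: int | None = None
    nor_loci: list[NorLocus] = field(default_factory=list)  # record-level aggregate
    x_linked_nor: bool | None = None
    first_pair_prominent: bool | None = None
    morphology_note: str = ""    # qualitative fallback when no pair list was printed

    def validate(self) -> list[str]:
        """Consistency checks; returns a list of human-readable problems."""
        problems: list[str] = []
        if self.diploid_number is not None and self.diploid_number % 2:
            problems.append(f"{self.taxon}: 2n={self.diploid_number} is odd")
        if self.pairs and self.diploid_number is not None:
            hi = self.diploid_number_max or self.diploid_number
            if not (self.diploid_number <= 2 * len(self.pairs) <= hi):
                problems.append(
                    f"{self.taxon}: {len(self.pairs)} pairs inconsistent with 2n={self.diploid_number}"
                )
        lengths = [p.rel_length for p in self.pairs if p.rel_length is not None]
        if lengths and len(lengths) == len(self.pairs):
            if abs(sum(lengths) - 100.0) > 1e-6:
                problems.append(f"{self.taxon}: rel_lengths sum to {sum(lengths)!r}, not 100")
        return problems


@dataclass(frozen=True)
class CompositionSummary:
    n_pairs: int
    n_biarmed: int
    n_monoarmed: int
    n_transitional_excluded: int
    biarmed_percent: float
    predominance: str  # biarmed_predominant | approximately_same | monoarmed_predominant
    partial: bool = False  # True when UNKNOWN-morphology pairs were present


def classify_morphology(
    short_arm: float,
    long_arm: float,
    boundary_tolerance: float = 0.05,
    bins: Sequence[tuple[MorphologyClass, float]] = DEFAULT_BINS,
) -> MorphologyClass:
    """Classify a chromosome by centromere position from its arm lengths.

    The arm ratio r = long/short is placed in the configured Levan-style
    bins. Edge proximity is judged on the centromeric-index scale
    ci = short/(short+long), where measurement error acts additively: when
    ci lies within ``boundary_tolerance`` (relative) of an interior bin
    edge's index the transitional composite of the two adjacent classes is
    returned, e.g. (2.6, 7.4) near the SM|ST edge gives SM/ST. A missing
    short arm is acrocentric by definition.
    """
    chrom = MeasuredChromosome(short_arm, long_arm)  # validates orientation
    r = chrom.arm_ratio
    if math.isinf(r):
        return MorphologyClass.A
    ci = 1.0 / (1.0 + r)
    for i, (cls, upper) in enumerate(bins[:-1]):
        ci_edge = 1.0 / (1.0 + upper)
        if abs(ci - ci_edge) <= boundary_tolerance * ci_edge:
            return _COMPOSITE.get((cls, bins[i + 1][0]), MorphologyClass.UNKNOWN)
    for cls, upper in bins:
        if r < upper or math.isinf(upper):
            return cls
    raise AssertionError("unreachable: last bin is open above")


def relative_pair_lengths(pair_lengths: Sequence[float]) -> list[float]:
    """Express pair lengths as percent of the total chromosome length.

    Input lengths may be per-pair sums over both homologs or uniformly
    haploid; %TCL is scale-free so either convention gives the same result
    as long as it is applied consistently.
    """
    if len(pair_lengths) == 0:
        raise ValueError("at least one pair length is required")
    if any(v <= 0 for v in pair_lengths):
        raise ValueError("pair lengths must be positive")
    total = float(sum(pair_lengths))
    return [100.0 * v / total for v in pair_lengths]


def composition_summary(
    record: KaryotypeRecord | Iterable[MorphologyClass],
    predominance_margin: int = 2,
) -> CompositionSummary:
    """Count biarmed vs monoarmed pairs and call the predominance.

    The proportion is "approximately the same" when the two counts differ
    by at most ``predominance_margin`` pairs (default two, the convention
    used for scoring these karyotypes); SM/ST transitional pairs are left
    out of the comparison but still counted in ``n_pairs`` and in the
    denominator of ``biarmed_percent``. The sex pair, when listed, counts
    like any other pair.
    """
    if isinstance(record, KaryotypeRecord):
        morphs = [p.morphology for p in record.pairs]
    else:
        morphs = list(record)
    n_pairs = len(morphs)
    if n_pairs == 0:
        raise ValueError("composition summary of an empty pair list")
    n_bi = sum(1 for m in morphs if m in _BIARMED)
    n_mono = sum(1 for m in morphs if m in _MONOARMED)
    n_unknown = sum(1 for m in morphs if m is MorphologyClass.UNKNOWN)
    n_trans = n_pairs - n_bi - n_mono - n_unknown  # SM/ST only
    diff = n_bi - n_mono
    if abs(diff) <= predominance_margin:
        predominance = "approximately_same"
    elif diff > 0:
        predominance = "biarmed_predominant"
    else:
        predominance = "monoarmed_predominant"
    return CompositionSummary(
        n_pairs=n_pairs,
        n_biarmed=n_bi,
        n_monoarmed=n_mono,
        n_transitional_excluded=n_trans,
        biarmed_percent=100.0 * n_bi / n_pairs,
        predominance=predominance,
        partial=n_unknown > 0,
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed percentages)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Compact pair-list grammar, e.g. "4m+3sm+1sm/st+27a" or "17bip+21monop"
# ---------------------------------------------------------------------------

_TOKEN_CLASSES = {
    "m": MorphologyClass.M,
    "sm": MorphologyClass.SM,
    "st": MorphologyClass.ST,
    "a": MorphologyClass.A,
    "m/sm": MorphologyClass.M_SM,
    "sm/st": MorphologyClass.SM_ST,
    "st/a": MorphologyClass.ST_A,
    "bi": MorphologyClass.BIARMED,
    "bip": MorphologyClass.BIARMED,
    "mono": MorphologyClass.MONOARMED,
    "monop": MorphologyClass.MONOARMED,
    "u": MorphologyClass.UNKNOWN,
}

_TERM_RE = re.compile(r"^(\d+)\s*([a-z/]+?)p?$")


def parse_pair_list(text: str) -> list[MorphologyClass]:
    """Parse a compact pair-list string into one morphology per pair.

    Grammar: terms joined by '+', each term COUNT CLASS where CLASS is one
    of m, sm, st, a, m/sm, sm/st, st/a, bip, monop, u (an optional trailing
    'p' for 'pair' is accepted, as in Table-style "4mp+3smp").
    """
    morphs: list[MorphologyClass] = []
    for raw in text.split("+"):
        term = raw.strip().lower()
        if not term:
            raise ValueError(f"empty term in pair list {text!r}")
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"cannot parse pair-list term {raw!r} in {text!r}")
        count, cls_token = int(m.group(1)), m.group(2)
        if cls_token not in _TOKEN_CLASSES:
            # retry with the trailing 'p' kept (handles 'monop' whose p is not a suffix)
            if term[len(m.group(1)):].strip() in _TOKEN_CLASSES:
                cls_token = term[len(m.group(1)):].strip()
            else:
                raise ValueError(f"unknown morphology token {cls_token!r} in {text!r}")
        morphs.extend([_TOKEN_CLASSES[cls_token]] * count)
    if not morphs:
        raise ValueError(f"pair list {text!r} parsed to zero pairs")
    return morphs
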