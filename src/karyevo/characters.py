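"""Discrete cytogenetic characters: schemes, matrices, encoding, decoding.

Each arachnid order gets its own character scheme: an ordered list of
characters, each with a state table mapping one-symbol codes (0-9 then A-G)
to meanings. A meaning is a numeric value, a numeric range, a small value
set, or a categorical label (e.g. a predominance call). '?' marks missing
data and is not a state.

``encode_record`` turns a :class:`~karyevo.karyotype.KaryotypeRecord` into
the taxon's state string; ``parse_matrix`` reads a printed taxon-by-state
matrix and validates every symbol against the scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import yaml

from .karyotype import (
    KaryotypeRecord,
    MorphologyClass,
    composition_summary,
)

__all__ = [
    "Character",
    "CharacterScheme",
    "CharacterMatrix",
    "UnencodableError",
    "parse_matrix",
    "format_matrix",
    "encode_record",
    "decode_state",
]

MISSING = "?"
SYMBOLS = "0123456789ABCDEFG"

# precedence when a karyotype carries NOR loci in several position classes:
# the rarer, more derived locations win the single-symbol summary
_NOR_LOCATION_PRECEDENCE = ("pericentric", "interstitial", "subterminal", "terminal")
_NOR_POSITION_BUCKET = {
    "terminal": "terminal",
    "whole_arm": "terminal",
    "subterminal": "subterminal",
    "interstitial": "interstitial",
    "pericentric": "pericentric",
}


class UnencodableError(ValueError):
    """A record's value fits no state of the character it must be coded by."""


@dataclass(frozen=True)
class Character:
    id: int
    name: str
    kind: str
    description: str
    states: Mapping[str, Any]  # code -> meaning (int | (lo, hi) | frozenset | str)

    def __post_init__(self) -> None:
        for code in self.states:
            if code not in SYMBOLS:
                raise ValueError(f"character {self.id}: illegal state code {code!r}")

    def code_for(self, value: Any) -> str | None:
        """State code whose meaning covers ``value``; None when no state does.

        ``value`` may be an int, an (lo, hi) int range (matched when fully
        covered), or a label string.
        """
        for code, meaning in self.states.items():
            if _meaning_covers(meaning, value):
                return code
        return None


def _meaning_covers(meaning: Any, value: Any) -> bool:
    if isinstance(value, str):
        return isinstance(meaning, str) and meaning == value
    lo, hi = (value, value) if isinstance(value, int) else value
    if isinstance(meaning, int):
        return lo == hi == meaning
    if isinstance(meaning, tuple):
        return meaning[0] <= lo and hi <= meaning[1]
    if isinstance(meaning, frozenset):
        return all(v in meaning for v in range(lo, hi + 1))
    return False


@dataclass(frozen=True)
class CharacterScheme:
    order: str
    characters: tuple[Character, ...]

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def character(self, char_id: int) -> Character:
        for c in self.characters:
            if c.id == char_id:
                return c
        raise KeyError(f"no character {char_id} in {self.order} scheme")

    @classmethod
    def from_yaml(cls, text: str) -> "CharacterScheme":
        doc = yaml.safe_load(text)
        chars = []
        for entry in doc["characters"]:
            states = {}
            for code, meaning in entry["states"].items():
                states[str(code)] = _parse_meaning(meaning)
            chars.append(
                Character(
                    id=int(entry["id"]),
                    name=entry["name"],
                    kind=entry["kind"],
                    description=entry.get("description", ""),
                    states=states,
                )
            )
        return cls(order=doc["order"], characters=tuple(chars))


def _parse_meaning(meaning: Any) -> Any:
    if isinstance(meaning, int):
        return meaning
    if isinstance(meaning, str):
        return meaning
    if isinstance(meaning, dict):
        if "value" in meaning:
            return int(meaning["value"])
        if "range" in meaning:
            lo, hi = meaning["range"]
            return (int(lo), int(hi))
        if "values" in meaning:
            return frozenset(int(v) for v in meaning["values"])
        if "label" in meaning:
            return str(meaning["label"])
    raise ValueError(f"cannot interpret state meaning {meaning!r}")


@dataclass
class CharacterMatrix:
    scheme: CharacterScheme
    taxa: list[str] = field(default_factory=list)
    rows: dict[str, str] = field(default_factory=dict)

    def state_of(self, taxon: str, char_id: int) -> str:
        row = self.rows[taxon]
        idx = [c.id for c in self.scheme.characters].index(char_id)
        return row[idx]

    def validate(self) -> None:
        n = self.scheme.n_characters
        for taxon, row in self.rows.items():
            if len(row) != n:
                raise ValueError(
                    f"{taxon}: state string {row!r} has length {len(row)}, expected {n}"
                )
            for ch, symbol in zip(self.scheme.characters, row):
                if symbol == MISSING:
                    continue
                if symbol not in ch.states:
                    raise ValueError(
                        f"{taxon}: symbol {symbol!r} not a state of character "
                        f"{ch.id} ({ch.name})"
                    )


def parse_matrix(text: str, scheme: CharacterScheme) -> CharacterMatrix:
    """Parse a TSV/whitespace matrix (taxon, state string) and validate it."""
    matrix = CharacterMatrix(scheme=scheme)
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.rsplit(None, 1)
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'taxon<TAB>states', got {line!r}")
        taxon, states = parts[0].strip(), parts[1].strip()
        if taxon in matrix.rows:
            raise ValueError(f"line {lineno}: duplicate taxon {taxon!r}")
        matrix.taxa.append(taxon)
        matrix.rows[taxon] = states
    matrix.validate()
    return matrix


def format_matrix(matrix: CharacterMatrix) -> str:
    return "\n".join(f"{t}\t{matrix.rows[t]}" for t in matrix.taxa) + "\n"


def decode_state(scheme: CharacterScheme, char_id: int, code: str) -> Any:
    """Meaning of one state code: int, (lo, hi) range, value set, or label."""
    character = scheme.character(char_id)
    if code not in character.states:
        raise KeyError(
            f"{code!r} is not a state of character {char_id} ({character.name})"
        )
    return character.states[code]


# ---------------------------------------------------------------------------
# Encoding KaryotypeRecords
# ---------------------------------------------------------------------------

_QUALITATIVE_PREDOMINANCE = {
    "monop_predominant": "monoarmed_predominant",
    "bip_predominant": "biarmed_predominant",
    "approximately_same": "approximately_same",
}


def _value_diploid_number(record: KaryotypeRecord) -> Any:
    if record.diploid_number is None:
        return None
    if record.diploid_number_max is not None:
        return (record.diploid_number, record.diploid_number_max)
    return record.diploid_number


def _value_predominance(record: KaryotypeRecord) -> Any:
    if record.pairs and any(
        p.morphology is not MorphologyClass.UNKNOWN for p in record.pairs
    ):
        return composition_summary(record).predominance
    return _QUALITATIVE_PREDOMINANCE.get(record.morphology_note)


def _value_nor_count(record: KaryotypeRecord, character: Character) -> Any:
    count = record.nor_locus_count
    if count is None:
        return None
    if character.code_for(count) is not None:
        return count
    # qualitative fallback states such as "most pairs carry one or two loci"
    if record.pairs and count >= len(record.pairs):
        for meaning in character.states.values():
            if isinstance(meaning, str):
                return meaning
    return count  # let encode raise UnencodableError with the number


def _value_nor_location(record: KaryotypeRecord) -> Any:
    if record.nor_locus_count is None:
        return None
    loci = list(record.nor_loci) or [
        locus for pair in record.pairs for locus in pair.nor_loci
    ]
    buckets = {_NOR_POSITION_BUCKET[locus.position] for locus in loci}
    if not buckets:
        return None
    for category in _NOR_LOCATION_PRECEDENCE:
        if category in buckets:
            return category
    return None


def _value_sex_differentiation(record: KaryotypeRecord) -> Any:
    if record.sex_system == "XY_heteromorphic":
        return "heteromorphic"
    if record.sex_system in ("none_detected", "XY_homomorphic"):
        return "none_or_homomorphic"
    return None


def _value_ch_pattern(record: KaryotypeRecord) -> Any:
    return {
        "low_centromeric_telomeric": "low",
        "enormous_blocks": "enormous",
    }.get(record.ch_pattern)


def _value_flag(flag: bool | None, true_label: str, false_label: str) -> Any:
    if flag is None:
        return None
    return true_label if flag else false_label


def encode_record(record: KaryotypeRecord, scheme: CharacterScheme) -> str:
    """Encode a karyotype record as its state string under ``scheme``.

    Fields the record lacks produce '?'. A present value that fits no
    state raises :class:`UnencodableError` naming the character (this is
    how out-of-range diploid numbers surface).
    """
    if record.order != scheme.order:
        raise ValueError(
            f"record order {record.order!r} does not match scheme {scheme.order!r}"
        )
    symbols: list[str] = []
    for character in scheme.characters:
        value = _extract_value(record, character)
        if value is None:
            symbols.append(MISSING)
            continue
        code = character.code_for(value)
        if code is None:
            raise UnencodableError(
                f"{record.taxon}: value {value!r} fits no state of character "
                f"{character.id} ({character.name})"
            )
        symbols.append(code)
    return "".join(symbols)


def _extract_value(record: KaryotypeRecord, character: Character) -> Any:
    kind = character.kind
    if kind == "diploid_number":
        return _value_diploid_number(record)
    if kind == "morphology_predominance":
        return _value_predominance(record)
    if kind == "nor_count":
        return _value_nor_count(record, character)
    if kind == "nor_location":
        return _value_nor_location(record)
    if kind == "sex_differentiation":
        return _value_sex_differentiation(record)
    if kind == "x_linked_nor":
        return _value_flag(record.x_linked_nor, "x_linked", "autosomal")
    if kind == "first_pair_size":
        return _value_flag(record.first_pair_prominent, "first_pair_larger", "gradual")
    if kind == "ch_pattern":
        return _value_ch_pattern(record)
    raise ValueError(f"unknown character kind {kind!r}")
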