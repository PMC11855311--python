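"""File formats, packaged fixtures and the pipeline runner.

All tabular I/O is plain TSV; trees are Newick; character schemes are YAML;
rearrangement scenarios are line-oriented structured text. The packaged
fixtures transcribe the study's karyotype table, the five character
matrices with their schemes, the order-level tree topologies and the
solifuge rearrangement scenarios.
"""

from __future__ import annotations

import csv
import io as _io
import logging
import sys
from importlib import resources
from typing import Any, Sequence

from .characters import (
    CharacterMatrix,
    CharacterScheme,
    encode_record,
    format_matrix,
    parse_matrix,
)
from .karyotype import (
    KaryotypePair,
    KaryotypeRecord,
    MorphologyClass,
    NorLocus,
    composition_summary,
    parse_pair_list,
)
from .meiosis import BivalentObservation, MeioticPlate
from .parsimony import RootedTree, reconstruct_root_karyotype
from .rearrangements import (
    KaryotypeComposition,
    RearrangementEvent,
    validate_scenario,
)

__all__ = [
    "FIXTURES",
    "load_fixture",
    "load_karyotype_table",
    "record_from_row",
    "load_plate_table",
    "parse_scenario_text",
    "run_pipeline",
]

log = logging.getLogger("karyevo")

# NOR location tokens -> (arm, position)
_NOR_TOKENS = {
    "NORt": ("unknown", "terminal"),
    "NORpt": ("short", "terminal"),
    "NORqt": ("long", "terminal"),
    "NORsubt": ("unknown", "subterminal"),
    "NORpsubt": ("short", "subterminal"),
    "NORqsubt": ("long", "subterminal"),
    "NORi": ("unknown", "interstitial"),
    "NORqi": ("long", "interstitial"),
    "NORperic": ("unknown", "pericentric"),
    "NORarm": ("unknown", "whole_arm"),
}

_ORDERS = ("amblypygi", "thelyphonida", "schizomida", "ricinulei", "solifugae")

FIXTURES: dict[str, tuple[str, str]] = {
    "karyotypes.table": ("table1_karyotypes.tsv", "karyotype table"),
    **{f"{o}.scheme": (f"scheme_{o}.yaml", "character scheme") for o in _ORDERS},
    **{f"{o}.matrix": (f"matrix_{o}.tsv", "character matrix") for o in _ORDERS},
    **{
        f"{o}.tree": (f"tree_{o}.nwk", "tree topology")
        for o in ("amblypygi", "schizomida", "ricinulei", "solifugae")
    },
    "schizomida.tree.alt_stenochrus": (
        "tree_schizomida_alt_stenochrus.nwk",
        "alternative tree topology",
    ),
    **{
        f"{n}.scenario": (f"scenario_{n}.txt", "rearrangement scenario")
        for n in ("eberlanzia", "solpugista", "gluvia")
    },
}


def _fixture_text(filename: str) -> str:
    return (resources.files("karyevo.fixtures") / filename).read_text(encoding="utf-8")


def load_fixture(name: str) -> Any:
    """Load a registered packaged fixture as its typed object.

    Names: ``karyotypes.table`` (list of KaryotypeRecord), ``<order>.scheme``
    (CharacterScheme), ``<order>.matrix`` (CharacterMatrix), ``<order>.tree``
    (RootedTree), ``<name>.scenario`` (start composition, events, expected).
    """
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; registered: {sorted(FIXTURES)}"
        )
    filename, _ = FIXTURES[name]
    text = _fixture_text(filename)
    if name == "karyotypes.table":
        return load_karyotype_table(text)
    if name.endswith(".scheme"):
        return CharacterScheme.from_yaml(text)
    if name.endswith(".matrix"):
        order = name.split(".")[0]
        scheme = load_fixture(f"{order}.scheme")
        return parse_matrix(text, scheme)
    if ".tree" in name:
        return RootedTree.from_newick(text)
    if name.endswith(".scenario"):
        return parse_scenario_text(text)
    raise AssertionError(f"unhandled fixture {name!r}")


# ---------------------------------------------------------------------------
# Karyotype tables
# ---------------------------------------------------------------------------

def record_from_row(row: dict[str, str]) -> KaryotypeRecord:
    """Build a KaryotypeRecord from one karyotype-table row."""
    def get(col: str) -> str:
        return (row.get(col) or "").strip()

    pairs: list[KaryotypePair] = []
    if get("composition"):
        morphs = parse_pair_list(get("composition"))
        pairs = [KaryotypePair(index=i + 1, morphology=m) for i, m in enumerate(morphs)]
    loci = []
    if get("nor_loci"):
        for token in get("nor_loci").split(";"):
            token = token.strip()
            if token not in _NOR_TOKENS:
                raise ValueError(f"{get('key')}: unknown NOR token {token!r}")
            arm, pos = _NOR_TOKENS[token]
            loci.append(NorLocus(arm=arm, position=pos))

    def flag(col: str) -> bool | None:
        v = get(col)
        return None if v == "" else bool(int(v))

    record = KaryotypeRecord(
        taxon=get("key") or get("taxon"),
        order=get("order"),
        diploid_number=int(get("two_n")) if get("two_n") else None,
        diploid_number_max=int(get("two_n_max")) if get("two_n_max") else None,
        pairs=pairs,
        sex_scored=get("sex_scored") or "unknown",
        sex_system=get("sex_system") or "unknown",
        telomere_motif="TTAGG_detected" if get("telomere") == "TTAGG" else "unknown",
        ch_pattern=get("ch_pattern") or "unknown",
        nor_locus_count=int(get("nor_count")) if get("nor_count") else None,
        nor_loci=loci,
        x_linked_nor=flag("x_linked_nor"),
        first_pair_prominent=flag("first_pair_prominent"),
        morphology_note=get("morphology_note"),
    )
    return record


def load_karyotype_table(text: str, strict: bool = True) -> list[KaryotypeRecord]:
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    records = [record_from_row(r) for r in reader]
    problems = [p for r in records for p in r.validate()]
    if problems and strict:
        raise ValueError("karyotype table validation failed:\n" + "\n".join(problems))
    for p in problems:
        log.warning("%s", p)
    return records


def write_summary_table(records: Sequence[KaryotypeRecord]) -> str:
    """Composition summaries of records that carry a pair list, as TSV."""
    buf = _io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["taxon", "order", "2n", "n_pairs", "n_biarmed", "n_monoarmed",
                "n_transitional_excluded", "biarmed_percent", "predominance"])
    for rec in records:
        if not rec.pairs:
            continue
        s = composition_summary(rec)
        w.writerow([rec.taxon, rec.order, rec.diploid_number, s.n_pairs, s.n_biarmed,
                    s.n_monoarmed, s.n_transitional_excluded,
                    f"{s.biarmed_percent:.4f}", s.predominance])
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Meiotic plate tables
# ---------------------------------------------------------------------------

def load_plate_table(text: str) -> list[MeioticPlate]:
    """TSV with columns plate_id, chromosome_length, centromere_position
    (or NA), chiasma_positions (semicolon-separated; empty allowed)."""
    by_plate: dict[str, list[BivalentObservation]] = {}
    order: list[str] = []
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    for row in csv.DictReader(lines, delimiter="\t"):
        pid = row["plate_id"].strip()
        if pid not in by_plate:
            by_plate[pid] = []
            order.append(pid)
        cen = row["centromere_position"].strip()
        chi = row.get("chiasma_positions", "").strip()
        by_plate[pid].append(
            BivalentObservation(
                chromosome_length=float(row["chromosome_length"]),
                centromere_position=None if cen.upper() in ("", "NA") else float(cen),
                chiasma_positions=tuple(
                    float(x) for x in chi.split(";") if x.strip()
                ),
            )
        )
    return [MeioticPlate(plate_id=p, bivalents=tuple(by_plate[p])) for p in order]


def write_plate_table(plates: Sequence[MeioticPlate]) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(["plate_id", "chromosome_length", "centromere_position", "chiasma_positions"])
    for plate in plates:
        for b in plate.bivalents:
            w.writerow([
                plate.plate_id,
                repr(b.chromosome_length),
                "NA" if b.centromere_position is None else repr(b.centromere_position),
                ";".join(repr(p) for p in b.chiasma_positions),
            ])
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Scenario files
# ---------------------------------------------------------------------------

def parse_scenario_text(
    text: str,
) -> tuple[KaryotypeComposition, list[RearrangementEvent], KaryotypeComposition | None]:
    """Parse a scenario file: start composition, events, optional expectation.

    Lines: ``start: a=12`` / ``sizes: 1.0,0.9,...`` / ``event: KIND SPEC``
    with SPEC ``x+y`` (fusion/fission operands), ``x->y`` (inversion), and
    optional ``@ i,j`` size-operand indices / ``expect: biarmed=2,st=2,a=7``.
    """
    start: KaryotypeComposition | None = None
    sizes: tuple[float, ...] | None = None
    events: list[RearrangementEvent] = []
    expect: KaryotypeComposition | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, rest = line.partition(":")
        key, rest = key.strip().lower(), rest.strip()
        if key == "start":
            start = KaryotypeComposition.parse(rest)
        elif key == "sizes":
            sizes = tuple(float(x) for x in rest.split(","))
        elif key == "expect":
            expect = KaryotypeComposition.parse(rest)
        elif key == "event":
            events.append(_parse_event(rest, lineno))
        else:
            raise ValueError(f"line {lineno}: unknown directive {key!r}")
    if start is None:
        raise ValueError("scenario file lacks a 'start:' line")
    if sizes is not None:
        start = KaryotypeComposition(
            biarmed=start.biarmed, st=start.st, a=start.a, sizes=sizes
        )
    return start, events, expect


def _parse_event(spec: str, lineno: int) -> RearrangementEvent:
    body, _, at = spec.partition("@")
    parts = body.split()
    kind = parts[0]
    operands: tuple[str, ...] = ()
    if len(parts) > 1:
        op = parts[1]
        if "->" in op:
            a, b = op.split("->")
            operands = (a.strip(), b.strip())
        elif "+" in op:
            a, b = op.split("+")
            operands = (a.strip(), b.strip())
        else:
            raise ValueError(f"line {lineno}: cannot parse operands {op!r}")
    size_operands = None
    if at.strip():
        size_operands = tuple(int(x) for x in at.strip().split(","))
    try:
        return RearrangementEvent(kind=kind, operands=operands, size_operands=size_operands)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Run the order-level analysis stages named in ``config``.

    Config keys: ``order`` (lowercase order name), ``stages`` (subset of
    ["summarize", "encode", "reconstruct", "scenario"]), optional
    ``tree_fixture`` override and ``scenario_names``. Fixture inputs are
    used throughout; stage failures raise with the stage named.
    """
    order = config.get("order", "").lower()
    stages = list(config.get("stages", []))
    report: dict[str, Any] = {"schema_version": 1, "order": order, "stages": {}}
    if not stages:
        return report
    if order not in _ORDERS:
        raise ValueError(f"unknown order {order!r}")

    records = [r for r in load_fixture("karyotypes.table") if r.order.lower() == order]
    for stage in stages:
        try:
            if stage == "summarize":
                report["stages"]["summarize"] = write_summary_table(records)
            elif stage == "encode":
                scheme = load_fixture(f"{order}.scheme")
                matrix = CharacterMatrix(scheme=scheme)
                for rec in records:
                    matrix.taxa.append(rec.taxon)
                    matrix.rows[rec.taxon] = encode_record(rec, scheme)
                matrix.validate()
                report["stages"]["encode"] = format_matrix(matrix)
            elif stage == "reconstruct":
                tree = load_fixture(config.get("tree_fixture", f"{order}.tree"))
                matrix = load_fixture(f"{order}.matrix")
                recon = reconstruct_root_karyotype(tree, matrix)
                report["stages"]["reconstruct"] = {
                    char_id: {
                        "root_states": sorted(info["root_states"]),
                        "meanings": [_meaning_str(m) for m in info["meanings"]],
                        "length": info["length"],
                    }
                    for char_id, info in recon.items()
                }
            elif stage == "scenario":
                results = {}
                for name in config.get(
                    "scenario_names", ["eberlanzia", "solpugista", "gluvia"]
                ):
                    start, events, expect = load_fixture(f"{name}.scenario")
                    end, rep = validate_scenario(
                        start, events, expected=expect,
                        size_aware=start.sizes is not None,
                    )
                    results[name] = {
                        "end": {"biarmed": end.biarmed, "st": end.st, "a": end.a,
                                "2n": end.diploid_number},
                        "n_events": rep["n_events"],
                        "event_counts": rep["event_counts"],
                        "matches_expected": rep["matches_expected"],
                    }
                report["stages"]["scenario"] = results
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return report


def _meaning_str(meaning: Any) -> str:
    if isinstance(meaning, tuple):
        return f"{meaning[0]}-{meaning[1]}"
    if isinstance(meaning, frozenset):
        return " or ".join(str(v) for v in sorted(meaning))
    return str(meaning)
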