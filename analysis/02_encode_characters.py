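#!/usr/bin/env python
"""Encode every karyotype record into its order's character-state string.

Runs the character encoder over all five orders and cross-checks the result
against the packaged (independently transcribed) matrices, row by row.
Writes results/matrices/<order>.tsv plus a concordance report. Any mismatch
would indicate a coding-rule regression, so the script exits non-zero on
disagreement.
"""

import sys
from pathlib import Path

from karyevo.characters import encode_record
from karyevo.io import load_fixture

ORDERS = ("amblypygi", "thelyphonida", "schizomida", "ricinulei", "solifugae")
OUT = Path(__file__).resolve().parents[1] / "results" / "matrices"


def main() -> None:
    records = load_fixture("karyotypes.table")
    OUT.mkdir(parents=True, exist_ok=True)
    total = mismatches = 0
    for order in ORDERS:
        scheme = load_fixture(f"{order}.scheme")
        printed = load_fixture(f"{order}.matrix")
        lines = []
        for rec in records:
            if rec.order.lower() != order:
                continue
            encoded = encode_record(rec, scheme)
            expected = printed.rows[rec.taxon]
            total += 1
            mark = ""
            if encoded != expected:
                mismatches += 1
                mark = f"\t# MISMATCH, transcribed row is {expected}"
            lines.append(f"{rec.taxon}\t{encoded}{mark}")
        (OUT / f"{order}.tsv").write_text("\n".join(lines) + "\n")
        print(f"{order}: encoded {len(lines)} taxa")
    print(f"concordance with transcribed matrices: {total - mismatches}/{total}")
    if mismatches:
        sys.exit(f"{mismatches} rows disagree with the transcribed matrices")


if __name__ == "__main__":
    main()
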