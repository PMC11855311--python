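import pytest

from karyevo import io as kio


@pytest.fixture(scope="session")
def records():
    return kio.load_fixture("karyotypes.table")


@pytest.fixture(scope="session")
def records_by_taxon(records):
    return {r.taxon: r for r in records}


@pytest.fixture(scope="session")
def schemes():
    return {
        order: kio.load_fixture(f"{order}.scheme")
        for order in ("amblypygi", "thelyphonida", "schizomida", "ricinulei", "solifugae")
    }


@pytest.fixture(scope="session")
def matrices():
    return {
        order: kio.load_fixture(f"{order}.matrix")
        for order in ("amblypygi", "thelyphonida", "schizomida", "ricinulei", "solifugae")
    }


@pytest.fixture(scope="session")
def trees():
    return {
        order: kio.load_fixture(f"{order}.tree")
        for order in ("amblypygi", "schizomida", "ricinulei", "solifugae")
    }
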