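from __future__ import annotations

import numpy as np
import pytest

from tsrnakit.reference import TRNARecord, parse_reference
from tsrnakit.simulate import CLOVERLEAF, SimConfig

# hand-annotated 76-nt cloverleaf fixture: loops at [14,21], [32,38], [54,60]
FIXTURE_SEQ = (
    "GCGGAUUUAGCUCAGUUGGGAGAGCGCCAGACUGAAGAUCUGGAGGUCCUGUGUUCGAUCCACAGAAUUCGCACCA"
)
FIXTURE_STRUCT = CLOVERLEAF
FIXTURE_TRAILER = "UUUCUGUUUUAUAGUUU"

FIXTURE_RECORD_TEXT = (
    f">fix-tRNA-Gly-1 Gly GCC precursor_trailer={FIXTURE_TRAILER}\n"
    f"{FIXTURE_SEQ}\n{FIXTURE_STRUCT}\n"
)


@pytest.fixture(scope="session")
def fixture_record(tmp_path_factory) -> TRNARecord:
    path = tmp_path_factory.mktemp("ref") / "fixture.txt"
    path.write_text(FIXTURE_RECORD_TEXT)
    records = parse_reference(path)
    assert len(records) == 1
    return records[0]


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(rng_seed=11, depth=5_000)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
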