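import random

import pytest

from ssrforge.primer_design import PrimerConstraints
from ssrforge.sequence_io import SequenceRecord
from ssrforge.ssr_scanner import ScanConfig


@pytest.fixture
def default_scan_config() -> ScanConfig:
    return ScanConfig()

@pytest.fixture
def default_constraints() -> PrimerConstraints:
    return PrimerConstraints()


@pytest.fixture
def record_factory():
    def make(seq: str, rec_id: str = "test", **kw) -> SequenceRecord:
        return SequenceRecord(id=rec_id, description="", seq=seq, **kw)
    return make


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))
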