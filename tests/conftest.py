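from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "covsize",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("covsize")

BASES = "ACGT"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20200629)


@pytest.fixture
def fastq_file(tmp_path):
    """Factory writing a FASTQ file from (id, seq) pairs or plain sequences."""

    def _write(seqs, name="reads.fq", qual_char="I"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for i, item in enumerate(seqs):
                rid, seq = item if isinstance(item, tuple) else (f"r{i}", item)
                fh.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")
        return path

    return _write


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))
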