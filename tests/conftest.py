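import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from magpop import TabularAlignment

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def make_aln():
    """Factory for gapless plus-strand alignment records with sane defaults."""

    counter = {"n": 0}

    def _make(
        pident: float,
        length: int = 100,
        sstart: int = 1,
        contig: str = "c1",
        qseqid: str | None = None,
        bitscore: float = 200.0,
    ) -> TabularAlignment:
        counter["n"] += 1
        return TabularAlignment(
            qseqid=qseqid or f"r{counter['n']}",
            sseqid=contig,
            pident=pident,
            length=length,
            mismatch=round(length * (100.0 - pident) / 100.0),
            gapopen=0,
            qstart=1,
            qend=length,
            sstart=sstart,
            send=sstart + length - 1,
            evalue=1e-30,
            bitscore=bitscore,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
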