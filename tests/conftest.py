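import pytest
from hypothesis import HealthCheck, settings

from lncdiscover import GenomeLayout, TranscriptModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 1_000_000, "chr2": 1_000_000})


def make_tx(tid="NR_000001", chrom="chr1", strand="+", start=10_000, end=12_000,
            exons=None, gene=None):
    return TranscriptModel(
        transcript_id=tid,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        exons=tuple(exons) if exons else ((start, end),),
        coding=not tid.startswith("NR_"),
        gene=gene,
    )


@pytest.fixture
def tx_factory():
    return make_tx
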