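import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from markdyn.genomic_io import GeneModel, GenomicInterval

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_gene(gene_id="g1", chrom="chr1", start=10_000, end=12_000, strand="+"):
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, end, strand=strand),
        transcript_id=f"{gene_id}.t1",
    )


@pytest.fixture
def plus_gene():
    return make_gene()


@pytest.fixture
def minus_gene():
    return make_gene(gene_id="g2", start=40_000, end=42_000, strand="-")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
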