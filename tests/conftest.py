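import numpy as np
import pytest

from lociforge.io_formats import GenotypePanel, SummaryStatRecord


@pytest.fixture
def tiny_panel():
    """Six-sample panel with three SNPs: two tightly linked, one independent."""
    # s1 and s2 nearly identical (one flip); s3 uncorrelated with both
    dosages = np.array([
        # s1 s2 s3
        [0, 0, 0],
        [0, 0, 1],
        [1, 1, 2],
        [1, 0, 0],
        [2, 2, 1],
        [2, 2, 2],
        [0, 0, 2],
        [2, 2, 0],
        [1, 1, 1],
        [1, 1, 2],
    ], dtype=float)
    return GenotypePanel(
        snp_ids=["s1", "s2", "s3"],
        chroms=["1", "1", "1"],
        positions=np.array([1000, 2000, 500_000]),
        dosages=dosages,
    )


def stat(snp_id, chrom, pos, p, **kw):
    return SummaryStatRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                             allele_ref="A", allele_alt="G", p=p, **kw)


@pytest.fixture
def stat_factory():
    return stat
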