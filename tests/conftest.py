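import numpy as np
import pytest

from pancscan.annotation import GeneModel
from pancscan.simulate import SimulationConfig, simulate_annotation


def make_gene(gene_id="gA", chrom="chr1", strand="+", tss=10000,
              length=3000, alts=None, cds=None):
    """Convenience builder for an isolated gene model."""
    if strand == "+":
        span = (tss, tss + length)
    else:
        span = (tss - length + 1, tss + 1)
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
        gene_span=span,
        cds_exons=cds if cds is not None else [(span[0] + 200, span[0] + 800)],
        tss_alternatives=alts or [tss],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured synthetic dataset shared across tests."""
    cfg = SimulationConfig(n_genes=400, seed=20240)
    return cfg, simulate_annotation(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(77)
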