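import numpy as np
import pytest

from chimerascope.pipeline import PipelineConfig, Resources
from chimerascope.refdb import load_annotation
from chimerascope.simulate import make_toy_reference


@pytest.fixture(scope="session")
def small_ref(tmp_path_factory):
    """Small synthetic reference: 2 x 300 kb chromosomes, 15 genes each."""
    d = tmp_path_factory.mktemp("smallref")
    fa, gtf = str(d / "toy.fa"), str(d / "toy.gtf")
    make_toy_reference(fa, gtf, n_chroms=2, chrom_len=300_000, genes_per_chrom=15, seed=1)
    return fa, gtf


@pytest.fixture(scope="session")
def small_db(small_ref):
    fa, gtf = small_ref
    return load_annotation(gtf, fa)


@pytest.fixture(scope="session")
def small_resources(small_db):
    return Resources.build(small_db, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
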