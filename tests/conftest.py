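import numpy as np
import pytest

from plastidsel.codon_core import get_code
from plastidsel.simulate import SimConfig, generate_study


@pytest.fixture(scope="session")
def code():
    return get_code(11)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small generated study shared by IO/pipeline tests."""
    outdir = tmp_path_factory.mktemp("study")
    cfg = SimConfig(n_genes=6, codons_per_gene=150, snps_per_gene=6,
                    omega_div=0.5, omega_poly=0.5, seed=101)
    truth = generate_study(cfg, outdir)
    return outdir, cfg, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
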