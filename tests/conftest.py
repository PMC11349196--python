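import numpy as np
import pytest

from vbfinemap.io import LDMatrix
from vbfinemap.ldmatrix import precompute
from vbfinemap.model import Hyperparams, VariationalState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_instance(rng, m=6, pi1=None, delta2=0.01):
    """A small random model instance (dense A, generic state/hyper).

    delta2 is kept moderate so finite differences stay well conditioned.
    """
    a = rng.normal(size=(m, m))
    z = rng.normal(size=m, scale=2.0)
    sld = precompute(a, z)
    hyper = Hyperparams(
        pi1=pi1 if pi1 is not None else rng.uniform(0.05, 0.5),
        sigma_beta2=rng.uniform(0.5, 2.0),
        sigma02=rng.uniform(0.5, 2.0),
        delta2=delta2,
    )
    state = VariationalState(
        q=rng.uniform(0.05, 0.95, m),
        mu=rng.normal(size=m, scale=0.5),
        sigma2=rng.uniform(0.05, 1.0, m),
    )
    return state, hyper, sld, z


@pytest.fixture
def small_sumstats_file(tmp_path):
    path = tmp_path / "sumstats.tsv"
    path.write_text(
        "SNP\tZ\tMAF\tN\n"
        "rs1\t1.0\t0.5\t1000\n"
        "rs2\t-2.0\t0.25\t1000\n"
        "rs3\t0.5\t0.1\t1000\n"
    )
    return path


@pytest.fixture
def identity_ld_file(tmp_path):
    path = tmp_path / "ld.txt"
    np.savetxt(path, np.eye(3), fmt="%.1f")
    return path


def block_ld_matrix(m, block=5, rho=0.8):
    """Deterministic block-AR(1) correlation matrix."""
    r = np.eye(m)
    for i in range(m):
        for j in range(m):
            if i // block == j // block:
                r[i, j] = rho ** abs(i - j)
    return LDMatrix(r=r)
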