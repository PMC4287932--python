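import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emtscore as es

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


@pytest.fixture
def small_matrix():
    """10 genes x 3 samples with distinct values per sample."""
    rng = np.random.default_rng(7)
    genes = [f"g{i:02d}" for i in range(10)]
    vals = rng.normal(7, 1, size=(10, 3))
    return es.matrix_from_arrays(genes, ["s1", "s2", "s3"], vals)


@pytest.fixture
def tiny_signature():
    return es.EMTSignature(epi_genes=("g00", "g01", "g02"),
                           mes_genes=("g07", "g08", "g09"))


def make_single_sample(values, genes=None):
    """Matrix with one sample named 's' from a list of values."""
    values = np.asarray(values, dtype=float)
    if genes is None:
        genes = [f"g{i:03d}" for i in range(len(values))]
    return es.matrix_from_arrays(genes, ["s"], values.reshape(-1, 1))


def brute_force_ks(epi, mes):
    """Independent KS oracle: scan every pooled value as a threshold.

    Returns (signed score, D) with the same sign convention: positive when
    the Epi ECDF exceeds the Mes ECDF at the supremum.
    """
    epi, mes = list(epi), list(mes)
    d_plus = d_minus = 0.0
    for t in sorted(set(epi) | set(mes)):
        fe = sum(v <= t for v in epi) / len(epi)
        fm = sum(v <= t for v in mes) / len(mes)
        d_plus = max(d_plus, fe - fm)
        d_minus = max(d_minus, fm - fe)
    d = max(d_plus, d_minus)
    if abs(d_plus - d_minus) <= 1e-12:
        return 0.0, d
    return (d_plus if d_plus > d_minus else -d_minus), d
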