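import numpy as np
import pytest

from sigconn import Signature


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_signature(rng, n_genes=20, prefix="G", sig_id="sig"):
    """Random z-score signature with p-values from the normal tail."""
    from scipy import stats

    d = rng.normal(size=n_genes)
    p = np.clip(2 * stats.norm.sf(np.abs(d)), 1e-12, 1.0)
    return Signature(
        gene_ids=np.array([f"{prefix}{i:04d}" for i in range(n_genes)], dtype=object),
        d=d,
        p=p,
        meta={"signature_id": sig_id},
    )


@pytest.fixture
def toy_signature():
    return Signature(
        gene_ids=np.array(["A", "B", "C", "D"], dtype=object),
        d=np.array([2.0, -1.5, 0.5, 1.0]),
        p=np.array([0.01, 0.1, 1.0, 0.5]),
        meta={"signature_id": "toy"},
    )
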