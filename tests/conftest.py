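import numpy as np
import pytest
import scipy.sparse as sp

import nucwrap as nw
from nucwrap import fixtures as F
from nucwrap.model import GaussianModel, _to_banded_upper
from nucwrap.seqops import ModSequence
from nucwrap.wrap import ConstraintSet


@pytest.fixture(scope="session")
def params():
    return F.synthetic_parameter_set(seed=1)


@pytest.fixture(scope="session")
def toy_model(params):
    return nw.build_model(ModSequence("ACGTACGTAC"), params)


def make_diag_model(n_coords, diag=None, mu=None):
    """Hand-built Gaussian model with an arbitrary (small) dimension,
    for identity checks that do not need a sequence."""
    d = np.ones(n_coords) if diag is None else np.asarray(diag, dtype=float)
    K = sp.csr_matrix(sp.diags(d))
    bw = 0
    ab = _to_banded_upper(K, bw)
    return GaussianModel(
        seq=ModSequence("AC"), n=2, N=n_coords,
        mu=np.zeros(n_coords) if mu is None else np.asarray(mu, dtype=float),
        K=K, K_banded=ab, meta={"scale": 10.0},
    )


def make_dense_model(K_dense, mu=None):
    K_dense = np.asarray(K_dense, dtype=float)
    N = K_dense.shape[0]
    K = sp.csr_matrix(K_dense)
    ab = _to_banded_upper(K, N - 1)
    return GaussianModel(
        seq=ModSequence("AC"), n=2, N=N,
        mu=np.zeros(N) if mu is None else np.asarray(mu, dtype=float),
        K=K, K_banded=ab, meta={"scale": 10.0},
    )


def mild_constraints(model, pairs, offsets, coefficient=5.0):
    """Constraints pulling ground-state phosphates by small offsets:
    well-conditioned toy problems with a known scale."""
    emb = nw.coords_to_frames(model.mu, model.n, scale=model.scale)
    refs = []
    for (s, j), off in zip(pairs, offsets):
        p = (emb.watson_phosphates[j - 1] if s == "W"
             else emb.crick_phosphates[j - 1])
        refs.append(p + np.asarray(off, dtype=float))
    return ConstraintSet([s for s, _ in pairs], [j for _, j in pairs],
                         np.array(refs),
                         np.full(len(pairs), float(coefficient)))
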