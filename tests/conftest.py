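import numpy as np
import pytest

import chromnest as cn


@pytest.fixture
def toy3():
    """3-bin ring matrix whose null model is tractable by hand:
    k=(2,2,2), 2m=6, P_01=1.2, P_02=0.6."""
    return cn.ContactMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))


def planted_matrix(blocks, boost=10.0, base=1.0, alpha=1.0):
    """Small deterministic matrix with fractal-globule decay and a
    within-block contact boost (no noise)."""
    blocks = np.asarray(blocks)
    n = blocks.size
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        decay = np.where(sep > 0, sep**-alpha, 0.0)
    e = base * decay * np.where(blocks[:, None] == blocks[None, :], boost, 1.0)
    np.fill_diagonal(e, 0.0)
    return cn.ContactMatrix(e)


@pytest.fixture
def planted6():
    """6-bin two-block matrix, 10x within-block boost over the decay."""
    return planted_matrix([0, 0, 0, 1, 1, 1])


@pytest.fixture(scope="session")
def hierarchy_run():
    """One 128-bin perfect-hierarchy synthetic run through the full
    community sweep (session-scoped: reused across test modules)."""
    spec = cn.SyntheticSpec(n_bins=128, seed=2)
    hierarchy = cn.synth_hierarchy(spec)
    matrix = cn.kr_balance(cn.synth_contact_matrix(spec, hierarchy)).scaled
    ps = cn.gamma_sweep(matrix, cn.default_gamma_grid(8), seed=0, restarts=5)
    domains = cn.extract_domains(ps)
    mt = cn.build_membership(ps, domains)
    return spec, hierarchy, matrix, ps, domains, mt
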