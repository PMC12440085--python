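import numpy as np
import pytest

import conndiff as cd


@pytest.fixture(scope="session")
def parcellation16():
    return cd.make_parcellation(16, seed=1)


@pytest.fixture(scope="session")
def parcellation30():
    return cd.make_parcellation(30, seed=7)


def make_fc(subject_id, z_edge, n_regions=2):
    """FCMatrix with a single common off-diagonal z value."""
    z = np.full((n_regions, n_regions), float(z_edge))
    np.fill_diagonal(z, 0.0)
    return cd.FCMatrix(subject_id=subject_id, z=z)


@pytest.fixture
def two_vs_two():
    """The hand-computed pooled-t fixture: A {0.2, 0.4} vs B {0.0, 0.2}.

    t = sqrt(2) on 2 df; two-sided p = 2 - sqrt(2) - ... = 0.2928932...
    computed from the closed-form Student-t(2) CDF.
    """
    fc_a = [make_fc("a1", 0.2), make_fc("a2", 0.4)]
    fc_b = [make_fc("b1", 0.0), make_fc("b2", 0.2)]
    return fc_a, fc_b


def student_t2_two_sided_p(t):
    """Closed-form two-sided p for Student t with 2 degrees of freedom.

    F(t) = 1/2 + t / (2*sqrt(2)*sqrt(1 + t^2/2)); independent of scipy.
    """
    t = abs(t)
    cdf = 0.5 + t / (2.0 * np.sqrt(2.0) * np.sqrt(1.0 + t * t / 2.0))
    return 2.0 * (1.0 - cdf)


@pytest.fixture
def random_fc_sets():
    """Seeded random FC matrices for invariance checks: 2 x (pre, post)."""
    rng = np.random.default_rng(42)
    n_regions = 6

    def draw(sid):
        m = rng.normal(scale=0.3, size=(n_regions, n_regions))
        z = (m + m.T) / 2
        return cd.FCMatrix(subject_id=sid, z=z)

    met_pre = [draw(f"m{k}") for k in range(4)]
    met_post = [draw(f"m{k}") for k in range(4)]
    pla_pre = [draw(f"p{k}") for k in range(4)]
    pla_post = [draw(f"p{k}") for k in range(4)]
    return met_pre, met_post, pla_pre, pla_post
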