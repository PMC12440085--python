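"""Statistical engine: pooled-variance t-tests, BH-FDR, significance weights.

All routines are vectorized over "features" (edges or regions).  Degenerate
zero-variance features are kept total rather than NaN: equal means give
p = 1, unequal means give the smallest positive normal double, and a
warning is logged so vectorized pipelines never silently drop features.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigError, ValidationError

logger = logging.getLogger(__name__)

#: p-value reported when a test statistic is formally infinite
MIN_P = float(np.finfo(float).tiny)

WEIGHT_SCHEMES = ("one_minus_q", "neglog10q")
TEST_CHOICES = ("student", "welch")


def _as_2d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValidationError(f"{name}: expected 1-D or 2-D array")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: non-finite values")
    return arr


def two_sample_t(a, b, test: str = "student") -> tuple[np.ndarray, np.ndarray]:
    """Two-sided two-sample t-test per column.

    Parameters
    ----------
    a, b : array-like, shape (n_subjects, n_features)
        Per-subject values in each condition.
    test : {"student", "welch"}
        Pooled-variance Student t (default) or Welch's unequal-variance t.

    Returns
    -------
    t, p : ndarray, shape (n_features,)
    """
    if test not in TEST_CHOICES:
        raise ConfigError(f"unknown test {test!r}; expected one of {TEST_CHOICES}")
    a = _as_2d(a, "a")
    b = _as_2d(b, "b")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValidationError(
            f"need at least 2 subjects per condition, got {na} and {nb}"
        )
    if a.shape[1] != b.shape[1]:
        raise ValidationError(
            f"feature count mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    d = a.mean(axis=0) - b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if test == "student":
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full_like(d, float(na + nb - 2))
        else:
            se = np.sqrt(va / na + vb / nb)
            num = (va / na + vb / nb) ** 2
            den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            df = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
        t = d / se
        p = 2.0 * sps.t.sf(np.abs(t), df)
    degenerate = se == 0
    if np.any(degenerate):
        eq = degenerate & (d == 0)
        ne = degenerate & (d != 0)
        t[eq] = 0.0
        p[eq] = 1.0
        t[ne] = np.sign(d[ne]) * np.inf
        p[ne] = MIN_P
        n_deg = int(ne.sum())
        if n_deg:
            logger.warning(
                "%d feature(s) had zero pooled variance with unequal means; "
                "p set to smallest positive normal", n_deg,
            )
            warnings.warn(
                f"{n_deg} degenerate zero-variance feature(s) with unequal "
                "means; p-value floored", RuntimeWarning, stacklevel=2,
            )
    return t, p


def bh_fdr(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values over one family.

    q_(i) = min_{k >= i} p_(k) * m / k, capped at 1, mapped back to input
    order; ``significant`` flags q <= alpha.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-D vector")
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must be finite and in [0, 1]")
    _check_alpha(alpha)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(p)
    q[order] = q_sorted
    return q, q <= alpha


def grouped_bh_fdr(p, group_label, alpha: float = 0.05
                   ) -> tuple[np.ndarray, np.ndarray]:
    """BH applied independently within each label's subset of p-values."""
    p = np.asarray(p, dtype=float)
    labels = np.asarray(group_label)
    if labels.shape != p.shape:
        raise ValidationError(
            f"group_label length {labels.size} != p length {p.size}"
        )
    q = np.empty_like(p)
    sig = np.empty(p.shape, dtype=bool)
    for lab in np.unique(labels):
        mask = labels == lab
        q[mask], sig[mask] = bh_fdr(p[mask], alpha)
    return q, sig


def significance_weight(delta_z, q, scheme: str = "one_minus_q"):
    """Significance-weighted effect magnitude for ribbon/bubble scaling.

    The default maps an edge's effect to ``|delta_z| * (1 - q)``: bounded,
    zero at q = 1, and monotone in both the effect magnitude and the
    evidence.  The alternative ``neglog10q`` scheme uses
    ``|delta_z| * (-log10 q)`` with q floored at the smallest positive
    normal so it stays finite.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ConfigError(
            f"unknown weight scheme {scheme!r}; expected one of {WEIGHT_SCHEMES}"
        )
    d = np.asarray(delta_z, dtype=float)
    qq = np.asarray(q, dtype=float)
    if np.any(qq < 0) or np.any(qq > 1) or not np.all(np.isfinite(qq)):
        raise ValidationError("q must be finite and in [0, 1]")
    if scheme == "one_minus_q":
        w = np.abs(d) * (1.0 - qq)
    else:
        w = np.abs(d) * (-np.log10(np.maximum(qq, MIN_P)))
    return w if w.ndim else float(w)


def interaction_delta_test(deltas_a, deltas_b) -> float:
    """Group x time interaction p for a balanced two-arm pre/post design.

    Implemented as the two-sided pooled-variance t-test on per-subject
    change scores, which coincides with the interaction test of the 2x2
    repeated-measures ANOVA when the within-subject factor has two levels
    (the interaction F is exactly t squared).
    """
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    _, p = two_sample_t(a[:, None], b[:, None], test="student")
    return float(p[0])


def _check_alpha(alpha: float) -> None:
    if not (0 < alpha < 1):
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
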