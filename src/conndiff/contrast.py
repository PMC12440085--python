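"""Edge-wise group contrasts: model and results objects.

Two designs are supported:

* Cross-sectional: ``EdgewiseContrast`` compares mean Fisher-z per edge
  between two independent groups (convention: A - B, e.g. the
  insulin-resistant group minus healthy controls at baseline).
* Longitudinal difference-in-differences: ``TreatmentContrast`` computes
  per-subject change matrices (post - pre) within each arm and contrasts
  the treated arm's changes against the control arm's, cancelling shared
  time trends and baseline offsets.  Positive delta_z means a greater
  connectivity increase under active treatment.

Raw (unthresholded) z values are used everywhere; the +/-0.05 noise band is
applied only later, for categorical interpretation of significant edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .fc import FCMatrix, edge_pairs
from .stats import (
    TEST_CHOICES,
    WEIGHT_SCHEMES,
    _check_alpha,
    bh_fdr,
    grouped_bh_fdr,
    significance_weight,
    two_sample_t,
)

FDR_FAMILIES = ("all_edges", "per_lobe_pair")

CONTRAST_COLUMNS = (
    "edge_i", "edge_j", "mean_a", "mean_b", "delta_z",
    "p", "q", "significant", "weight",
)


@dataclass
class ChangeMatrix:
    """Per-subject post-minus-pre Fisher-z change; NaN diagonal."""

    subject_id: str
    dz: np.ndarray

    def __post_init__(self) -> None:
        wrapped = FCMatrix(subject_id=self.subject_id, z=self.dz)
        self.dz = wrapped.z

    @property
    def n_regions(self) -> int:
        return self.dz.shape[0]

    def edge_values(self) -> np.ndarray:
        i, j = np.triu_indices(self.n_regions, k=1)
        return self.dz[i, j]


def subject_change(pre: FCMatrix, post: FCMatrix) -> ChangeMatrix:
    """Entrywise post - pre for one subject's paired scans."""
    if pre.subject_id != post.subject_id:
        raise ValidationError(
            f"pre/post subject mismatch: {pre.subject_id!r} vs "
            f"{post.subject_id!r}"
        )
    if pre.n_regions != post.n_regions:
        raise ValidationError(
            f"subject {pre.subject_id}: dimension mismatch "
            f"{pre.n_regions} vs {post.n_regions}"
        )
    return ChangeMatrix(subject_id=pre.subject_id, dz=post.z - pre.z)


def _stack_edges(matrices: Sequence[FCMatrix | ChangeMatrix],
                 label: str) -> np.ndarray:
    if len(matrices) < 2:
        raise ValidationError(
            f"condition {label!r}: need at least 2 subjects, "
            f"got {len(matrices)}"
        )
    sizes = {m.n_regions for m in matrices}
    if len(sizes) != 1:
        raise ValidationError(
            f"condition {label!r}: inconsistent region counts {sorted(sizes)}"
        )
    return np.vstack([m.edge_values() for m in matrices])


class EdgewiseContrast:
    """Edge-wise two-group contrast on Fisher-z connectivity.

    Parameters
    ----------
    fc_a, fc_b : sequences of FCMatrix (or ChangeMatrix)
        Per-subject matrices in each condition; delta_z is mean(A) - mean(B).
    alpha : float
        FDR level for flagging edges (default 0.05).
    test : {"student", "welch"}
        Edge-level test; pooled-variance Student t by default.
    weight_scheme : {"one_minus_q", "neglog10q"}
        Significance weighting of |delta_z| for ribbon widths.
    fdr_family : {"all_edges", "per_lobe_pair"}
        Correction family; the default corrects over all R(R-1)/2 edges
        jointly.  "per_lobe_pair" needs ``region_lobes``.
    region_lobes : sequence of str, optional
        Per-region lobe labels (required for fdr_family="per_lobe_pair").
    kind : {"cross_sectional", "longitudinal"}
        Recorded on the results for bookkeeping.
    """

    def __init__(self, fc_a, fc_b, *, alpha: float = 0.05,
                 test: str = "student", weight_scheme: str = "one_minus_q",
                 fdr_family: str = "all_edges",
                 region_lobes: Sequence[str] | None = None,
                 kind: str = "cross_sectional") -> None:
        _check_alpha(alpha)
        if test not in TEST_CHOICES:
            raise ValidationError(f"unknown test {test!r}")
        if weight_scheme not in WEIGHT_SCHEMES:
            raise ValidationError(f"unknown weight scheme {weight_scheme!r}")
        if fdr_family not in FDR_FAMILIES:
            raise ValidationError(f"unknown fdr family {fdr_family!r}")
        self.a = _stack_edges(fc_a, "A")
        self.b = _stack_edges(fc_b, "B")
        if self.a.shape[1] != self.b.shape[1]:
            raise ValidationError("conditions have different region counts")
        self.n_regions = fc_a[0].n_regions
        self.alpha = float(alpha)
        self.test = test
        self.weight_scheme = weight_scheme
        self.fdr_family = fdr_family
        self.region_lobes = (
            list(region_lobes) if region_lobes is not None else None
        )
        if fdr_family == "per_lobe_pair" and self.region_lobes is None:
            raise ValidationError(
                "fdr_family='per_lobe_pair' requires region_lobes"
            )
        self.kind = kind

    def fit(self) -> "EdgewiseContrastResults":
        mean_a = self.a.mean(axis=0)
        mean_b = self.b.mean(axis=0)
        t, p = two_sample_t(self.a, self.b, test=self.test)
        if self.fdr_family == "all_edges":
            q, sig = bh_fdr(p, self.alpha)
        else:
            i, j = edge_pairs(self.n_regions)
            lobes = self.region_lobes
            fam = np.array([
                "|".join(sorted((lobes[a], lobes[b]))) for a, b in zip(i, j)
            ])
            q, sig = grouped_bh_fdr(p, fam, self.alpha)
        weight = significance_weight(mean_a - mean_b, q, self.weight_scheme)
        return EdgewiseContrastResults(
            model=self, mean_a=mean_a, mean_b=mean_b, t=t, p=p, q=q,
            significant=sig, weight=weight,
        )


class EdgewiseContrastResults:
    """Fitted edge-wise contrast: one record per unordered region pair."""

    def __init__(self, model: EdgewiseContrast, mean_a, mean_b, t, p, q,
                 significant, weight) -> None:
        self.model = model
        self.n_regions = model.n_regions
        self.edge_i, self.edge_j = edge_pairs(self.n_regions)
        self.mean_a = np.asarray(mean_a)
        self.mean_b = np.asarray(mean_b)
        self.delta_z = self.mean_a - self.mean_b
        self.t = np.asarray(t)
        self.p = np.asarray(p)
        self.q = np.asarray(q)
        self.significant = np.asarray(significant, dtype=bool)
        self.weight = np.asarray(weight)
        self.alpha = model.alpha
        self.kind = model.kind

    @property
    def n_edges(self) -> int:
        return self.p.size

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-edge table, deterministic edge order."""
        return pd.DataFrame({
            "edge_i": self.edge_i,
            "edge_j": self.edge_j,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "delta_z": self.delta_z,
            "p": self.p,
            "q": self.q,
            "significant": self.significant,
            "weight": self.weight,
        })

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.10g")

    def summary(self) -> str:
        """Human-readable overview of the fitted contrast."""
        sig = self.significant
        lines = [
            f"Edge-wise {self.kind} contrast "
            f"({self.model.test} t, BH-FDR alpha={self.alpha:g})",
            f"  regions: {self.n_regions}   edges: {self.n_edges}",
            f"  subjects: A n={self.model.a.shape[0]}, "
            f"B n={self.model.b.shape[0]}",
            f"  significant edges (q <= {self.alpha:g}): {int(sig.sum())}",
        ]
        if sig.any():
            lines += [
                f"    delta_z > 0 (stronger in A): {int((self.delta_z[sig] > 0).sum())}",
                f"    delta_z < 0 (stronger in B): {int((self.delta_z[sig] < 0).sum())}",
                f"    |delta_z| range among significant: "
                f"[{np.abs(self.delta_z[sig]).min():.4f}, "
                f"{np.abs(self.delta_z[sig]).max():.4f}]",
            ]
        return "\n".join(lines)

    def classify(self, threshold: float = 0.05) -> pd.DataFrame:
        """Directionally classify significant edges via the noise band."""
        from .classify import classify_contrast
        return classify_contrast(self, threshold=threshold)


class TreatmentContrast:
    """Placebo-subtracted treatment effect on connectivity.

    Computes per-subject change matrices within each arm (subjects paired
    by id between the pre and post lists) and contrasts treated changes
    (condition A) against control changes (condition B).
    """

    def __init__(self, treated_pre, treated_post, control_pre, control_post,
                 *, alpha: float = 0.05, test: str = "student",
                 weight_scheme: str = "one_minus_q",
                 fdr_family: str = "all_edges",
                 region_lobes: Sequence[str] | None = None) -> None:
        self.treated_changes = pair_changes(treated_pre, treated_post, "treated")
        self.control_changes = pair_changes(control_pre, control_post, "control")
        self._opts = dict(alpha=alpha, test=test,
                          weight_scheme=weight_scheme,
                          fdr_family=fdr_family, region_lobes=region_lobes)

    def fit(self) -> EdgewiseContrastResults:
        model = EdgewiseContrast(
            self.treated_changes, self.control_changes,
            kind="longitudinal", **self._opts,
        )
        return model.fit()


def pair_changes(pre: Sequence[FCMatrix], post: Sequence[FCMatrix],
                 arm: str) -> list[ChangeMatrix]:
    """Match pre/post scans by subject id and return change matrices."""
    pre_by_id = {m.subject_id: m for m in pre}
    post_by_id = {m.subject_id: m for m in post}
    if len(pre_by_id) != len(pre) or len(post_by_id) != len(post):
        raise ValidationError(f"arm {arm!r}: duplicate subject ids")
    unpaired = sorted(set(pre_by_id) ^ set(post_by_id))
    if unpaired:
        raise ValidationError(
            f"arm {arm!r}: unpaired subject(s) {unpaired}"
        )
    return [
        subject_change(pre_by_id[sid], post_by_id[sid])
        for sid in sorted(pre_by_id)
    ]


# -------------------------------------------------------------------------
# Functional wrappers (thin aliases over the model classes)
# -------------------------------------------------------------------------

def edgewise_group_contrast(fc_a, fc_b, alpha: float = 0.05,
                            **kwargs) -> EdgewiseContrastResults:
    """Fit an edge-wise A-vs-B contrast; see ``EdgewiseContrast``."""
    return EdgewiseContrast(fc_a, fc_b, alpha=alpha, **kwargs).fit()


def treatment_contrast(treated_pre, treated_post, control_pre, control_post,
                       alpha: float = 0.05, **kwargs
                       ) -> EdgewiseContrastResults:
    """Fit the difference-in-differences contrast; see ``TreatmentContrast``."""
    return TreatmentContrast(
        treated_pre, treated_post, control_pre, control_post,
        alpha=alpha, **kwargs,
    ).fit()
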