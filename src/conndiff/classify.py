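"""Noise-band directional classification and anatomical aggregation.

A Fisher-z value inside the band (-threshold, +threshold) — default
+/-0.05 — is "effectively zero": too small to call positive or negative
connectivity.  Significant edges are classified by where the group (or
timepoint) means sit relative to the band, so that transitions from weak
to strong coupling are named rather than noise-level sign flips.  The band
is applied only here, for interpretation; all testing upstream uses raw
values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError
from .regions import RegionMeta, level_vocabulary, labels_for, validate_regions

SIGN_POSITIVE = "P"
SIGN_ZERO = "Z"
SIGN_NEGATIVE = "N"

CROSS_SECTIONAL_CATEGORIES = (
    "stronger_positive_in_A",
    "stronger_positive_in_B",
    "stronger_negative_in_A",
    "stronger_negative_in_B",
    "indeterminate",
)

LONGITUDINAL_CATEGORIES = (
    "more_positive",
    "less_positive",
    "more_negative",
    "less_negative",
    "sign_transition",
    "indeterminate",
)

#: sentinel returned when classification is requested on a non-significant edge
NOT_CLASSIFIED = "not_classified"


def band_sign(z: float, threshold: float = 0.05) -> str:
    """Banded sign: P if z >= +threshold, N if z <= -threshold, else Z.

    The boundary |z| = threshold counts as meaningful connectivity (the
    band is an open interval).
    """
    if threshold <= 0:
        raise ConfigError(f"threshold must be positive, got {threshold}")
    if not np.isfinite(z):
        raise ValidationError(f"non-finite z value {z}")
    if z >= threshold:
        return SIGN_POSITIVE
    if z <= -threshold:
        return SIGN_NEGATIVE
    return SIGN_ZERO


def classify_cross_sectional(mean_a: float, mean_b: float,
                             significant: bool = True,
                             threshold: float = 0.05) -> str:
    """Directional category of a significant A-vs-B edge.

    With d = mean_a - mean_b, the edge is attributed to the group whose
    mean lies outside the band on the side consistent with the sign of d.
    When both groups qualify (one clearly positive, the other clearly
    negative), the group with the larger |mean| wins; an exact tie prefers
    the positive category.  Both means inside the band -> indeterminate.
    """
    if not significant:
        return NOT_CLASSIFIED
    d = mean_a - mean_b
    sa = band_sign(mean_a, threshold)
    sb = band_sign(mean_b, threshold)
    candidates = []
    if d > 0 and sa == SIGN_POSITIVE:
        candidates.append("stronger_positive_in_A")
    if d < 0 and sb == SIGN_POSITIVE:
        candidates.append("stronger_positive_in_B")
    if d < 0 and sa == SIGN_NEGATIVE:
        candidates.append("stronger_negative_in_A")
    if d > 0 and sb == SIGN_NEGATIVE:
        candidates.append("stronger_negative_in_B")
    if not candidates:
        return "indeterminate"
    if len(candidates) == 1:
        return candidates[0]
    # double match: one group clearly positive, the other clearly negative
    if abs(mean_a) != abs(mean_b):
        winner_is_a = abs(mean_a) > abs(mean_b)
    else:
        # exact tie: prefer the positive category
        winner_is_a = sa == SIGN_POSITIVE
    for cat in candidates:
        if cat.endswith("in_A") == winner_is_a:
            return cat
    return candidates[0]  # pragma: no cover - unreachable by construction


def classify_longitudinal(mean_pre: float, mean_post: float,
                          significant: bool = True,
                          threshold: float = 0.05) -> str:
    """Directional category of a significant pre-vs-post edge.

    Uses banded pre/post signs so only transitions through meaningful
    levels are named; a full positive<->negative crossing gets its own
    ``sign_transition`` label, and edges whose means stay inside the band
    are indeterminate.
    """
    if not significant:
        return NOT_CLASSIFIED
    delta = mean_post - mean_pre
    sp = band_sign(mean_pre, threshold)
    so = band_sign(mean_post, threshold)
    if {sp, so} == {SIGN_POSITIVE, SIGN_NEGATIVE}:
        return "sign_transition"
    if so == SIGN_POSITIVE and delta > 0 and sp in (SIGN_POSITIVE, SIGN_ZERO):
        return "more_positive"
    if sp == SIGN_POSITIVE and delta < 0 and so in (SIGN_POSITIVE, SIGN_ZERO):
        return "less_positive"
    if so == SIGN_NEGATIVE and delta < 0 and sp in (SIGN_NEGATIVE, SIGN_ZERO):
        return "more_negative"
    if sp == SIGN_NEGATIVE and delta > 0 and so in (SIGN_NEGATIVE, SIGN_ZERO):
        return "less_negative"
    return "indeterminate"


def count_categories(categories: Iterable[str]) -> pd.DataFrame:
    """Tally categories and their proportions of all classified edges."""
    cats = list(categories)
    counts: dict[str, int] = {}
    for c in cats:
        counts[c] = counts.get(c, 0) + 1
    total = len(cats)
    rows = [
        (c, n, (n / total if total else 0.0))
        for c, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["category", "count", "proportion"])


def classify_contrast(results, threshold: float = 0.05,
                      meta: Sequence[RegionMeta] | None = None
                      ) -> pd.DataFrame:
    """Classify the significant edges of a fitted cross-sectional contrast.

    Returns one row per significant edge: indices, category, effect,
    q-value, weight, and (when ``meta`` is given) lobe/network labels.
    """
    if results.kind != "cross_sectional":
        raise ValidationError(
            "classify_contrast applies to cross-sectional results; use "
            "classify_longitudinal_table with per-arm pre/post means"
        )
    mask = results.significant
    cats = [
        classify_cross_sectional(a, b, True, threshold)
        for a, b in zip(results.mean_a[mask], results.mean_b[mask])
    ]
    return _classified_frame(results, mask, cats, meta)


def classify_longitudinal_table(results, mean_pre: np.ndarray,
                                mean_post: np.ndarray,
                                threshold: float = 0.05,
                                meta: Sequence[RegionMeta] | None = None
                                ) -> pd.DataFrame:
    """Classify treatment-significant edges using one arm's pre/post means.

    ``mean_pre``/``mean_post`` are per-edge mean z vectors for the arm being
    interpreted (classification is per arm; significance comes from the
    placebo-subtracted contrast in ``results``).
    """
    mean_pre = np.asarray(mean_pre, dtype=float)
    mean_post = np.asarray(mean_post, dtype=float)
    if mean_pre.shape != (results.n_edges,) or mean_post.shape != (results.n_edges,):
        raise ValidationError("pre/post mean vectors must have one value per edge")
    mask = results.significant
    cats = [
        classify_longitudinal(pre, post, True, threshold)
        for pre, post in zip(mean_pre[mask], mean_post[mask])
    ]
    return _classified_frame(results, mask, cats, meta)


def _classified_frame(results, mask, cats, meta) -> pd.DataFrame:
    df = pd.DataFrame({
        "edge_i": results.edge_i[mask],
        "edge_j": results.edge_j[mask],
        "category": cats,
        "delta_z": results.delta_z[mask],
        "q": results.q[mask],
        "weight": results.weight[mask],
    })
    if meta is not None:
        regions = validate_regions(list(meta))
        for level in ("lobe", "network"):
            labels = labels_for(regions, level)
            df[f"{level}_i"] = [labels[i] for i in df["edge_i"]]
            df[f"{level}_j"] = [labels[j] for j in df["edge_j"]]
    return df


@dataclass
class PairTable:
    """Symmetric label-pair count and weight matrices at one grouping level."""

    level: str
    labels: tuple[str, ...]
    counts: np.ndarray
    weights: np.ndarray

    @property
    def total_edges(self) -> int:
        """Upper triangle + diagonal of counts = number of classified edges."""
        return int(np.triu(self.counts).sum())

    @property
    def total_weight(self) -> float:
        return float(np.triu(self.weights).sum())

    def to_frame(self, which: str = "counts") -> pd.DataFrame:
        m = self.counts if which == "counts" else self.weights
        return pd.DataFrame(m, index=list(self.labels),
                            columns=list(self.labels))


def aggregate_pairs(classified: pd.DataFrame, meta: Sequence[RegionMeta],
                    level: str) -> PairTable:
    """Fold classified edges into a label-by-label pair table.

    Each edge increments the symmetric count cell of its endpoint labels
    and adds its weight; within-label edges land on the diagonal (counted
    once in the upper-triangle total).
    """
    regions = validate_regions(list(meta))
    labels = labels_for(regions, level)
    vocab = level_vocabulary(level)
    index = {lab: k for k, lab in enumerate(vocab)}
    n = len(vocab)
    counts = np.zeros((n, n), dtype=int)
    weights = np.zeros((n, n), dtype=float)
    n_regions = len(regions)
    for row in classified.itertuples(index=False):
        i, j = int(row.edge_i), int(row.edge_j)
        for rid in (i, j):
            if not 0 <= rid < n_regions:
                raise ValidationError(
                    f"unknown region_id {rid} (parcellation has "
                    f"{n_regions} regions)"
                )
        a, b = index[labels[i]], index[labels[j]]
        counts[a, b] += 1
        weights[a, b] += float(row.weight)
        if a != b:
            counts[b, a] += 1
            weights[b, a] += float(row.weight)
    return PairTable(level=level, labels=vocab, counts=counts, weights=weights)


def hub_table(classified: pd.DataFrame,
              meta: Sequence[RegionMeta] | None = None) -> pd.DataFrame:
    """Per-region connection counts and weights over classified edges.

    Sorted by degree descending, then total weight descending, then
    region_id ascending; the strongest partner is the other endpoint of
    each region's maximum-weight edge.
    """
    degree: dict[int, int] = {}
    weight: dict[int, float] = {}
    best: dict[int, tuple[float, int]] = {}
    for row in classified.itertuples(index=False):
        i, j = int(row.edge_i), int(row.edge_j)
        w = float(row.weight)
        for a, b in ((i, j), (j, i)):
            degree[a] = degree.get(a, 0) + 1
            weight[a] = weight.get(a, 0.0) + w
            if a not in best or w > best[a][0]:
                best[a] = (w, b)
    rows = []
    names = None
    if meta is not None:
        regions = validate_regions(list(meta))
        names = {r.region_id: r.name for r in regions}
    for rid in degree:
        rows.append({
            "region_id": rid,
            **({"name": names[rid]} if names else {}),
            "n_connections": degree[rid],
            "total_weight": weight[rid],
            "strongest_partner": best[rid][1],
        })
    df = pd.DataFrame(rows)
    if df.empty:
        cols = ["region_id"] + (["name"] if names else []) + [
            "n_connections", "total_weight", "strongest_partner"]
        return pd.DataFrame(columns=cols)
    return df.sort_values(
        by=["n_connections", "total_weight", "region_id"],
        ascending=[False, False, True],
    ).reset_index(drop=True)


def export_chord_table(pair_table: PairTable, path: str | Path) -> None:
    """Write a long-format ribbon table for chord-diagram rendering.

    One row per unordered label pair with a nonzero count:
    from_label, to_label, count, weight.
    """
    rows = []
    n = len(pair_table.labels)
    for a in range(n):
        for b in range(a, n):
            c = int(pair_table.counts[a, b])
            if c:
                rows.append((
                    pair_table.labels[a], pair_table.labels[b],
                    c, float(pair_table.weights[a, b]),
                ))
    pd.DataFrame(
        rows, columns=["from_label", "to_label", "count", "weight"]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_chord_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
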