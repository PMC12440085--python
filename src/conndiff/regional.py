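"""Regional scalar statistics: uptake ratios, normalized volumes,
group comparisons, marker regressions and pre/post interaction tests.

This layer mirrors the region-level analyses that accompany a connectivity
study: FDG-PET uptake expressed as a standardized uptake value ratio
(SUVr, regional uptake over pons uptake), structural volumes normalized to
estimated total intracranial volume (eTIV), two-group comparisons per
region, and per-region simple linear regressions against a fasting marker.
Multiple testing is corrected with Benjamini-Hochberg applied within each
anatomical lobe, matching the convention of grouping regions by anatomical
position before FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError
from .stats import MIN_P, grouped_bh_fdr, interaction_delta_test, two_sample_t


def suvr(regional_uptake: float, pons_uptake: float) -> float:
    """Standardized uptake value ratio: regional uptake / pons uptake."""
    if not (pons_uptake > 0):
        raise ValidationError(
            f"pons uptake must be positive, got {pons_uptake}"
        )
    if not (regional_uptake >= 0) or not np.isfinite(regional_uptake):
        raise ValidationError(
            f"regional uptake must be nonnegative and finite, "
            f"got {regional_uptake}"
        )
    return float(regional_uptake) / float(pons_uptake)


def normalize_to_etiv(volume: float, etiv: float) -> float:
    """Regional volume as a fraction of estimated intracranial volume."""
    if not (etiv > 0):
        raise ValidationError(f"eTIV must be positive, got {etiv}")
    if not (volume >= 0) or not np.isfinite(volume):
        raise ValidationError(
            f"volume must be nonnegative and finite, got {volume}"
        )
    return float(volume) / float(etiv)


def _region_lobes(regions: Sequence[str],
                  lobe_map: Mapping[str, str]) -> np.ndarray:
    missing = [r for r in regions if r not in lobe_map]
    if missing:
        raise ValidationError(f"region(s) missing from lobe map: {missing}")
    return np.array([lobe_map[r] for r in regions])


def compare_groups_by_region(values: pd.DataFrame, group_col: str,
                             lobe_map: Mapping[str, str],
                             alpha: float = 0.05,
                             value_col: str = "value",
                             region_col: str = "region") -> pd.DataFrame:
    """Per-region two-sided pooled-t group comparison with within-lobe FDR.

    ``values`` is long-format with one row per subject x region; the two
    levels of ``group_col`` define the comparison (first level sorted
    lexicographically is condition A).  Every subject must have a value
    for every region.
    """
    groups = sorted(values[group_col].unique())
    if len(groups) != 2:
        raise ValidationError(
            f"expected exactly 2 groups, got {groups}"
        )
    regions = sorted(values[region_col].unique())
    counts = values.groupby([region_col, group_col]).size()
    expected = values.groupby(group_col)["subject_id"].nunique()
    gaps = [
        (r, g) for r in regions for g in groups
        if counts.get((r, g), 0) != expected[g]
    ]
    if gaps:
        raise ValidationError(f"missing subject values for region/group: {gaps}")
    rows = []
    for region in regions:
        sub = values[values[region_col] == region]
        a = sub.loc[sub[group_col] == groups[0], value_col].to_numpy()
        b = sub.loc[sub[group_col] == groups[1], value_col].to_numpy()
        t, p = two_sample_t(a[:, None], b[:, None])
        rows.append({
            "region": region,
            "lobe": None,
            "mean_a": a.mean(),
            "mean_b": b.mean(),
            "t": t[0],
            "p": p[0],
        })
    out = pd.DataFrame(rows)
    out["lobe"] = _region_lobes(out["region"], lobe_map)
    out["q"], out["significant"] = grouped_bh_fdr(
        out["p"].to_numpy(), out["lobe"].to_numpy(), alpha
    )
    return out


class MarkerRegression:
    """Per-region simple linear regression of a value against a marker.

    Each region's values across subjects are regressed on a per-subject
    scalar marker (e.g. fasting glucose) by ordinary least squares; slope
    p-values are corrected within anatomical lobes.
    """

    def __init__(self, values: pd.DataFrame, marker: pd.Series | Mapping,
                 lobe_map: Mapping[str, str], alpha: float = 0.05,
                 value_col: str = "value", region_col: str = "region"):
        self.values = values
        self.marker = pd.Series(marker)
        self.lobe_map = lobe_map
        self.alpha = alpha
        self.value_col = value_col
        self.region_col = region_col
        if self.marker.nunique() < 2:
            raise ValidationError("marker is constant; regression undefined")

    def fit(self) -> "MarkerRegressionResults":
        rows = []
        for region, sub in self.values.groupby(self.region_col):
            merged = sub.set_index("subject_id")[self.value_col].to_frame()
            merged["marker"] = self.marker
            merged = merged.dropna()
            n = len(merged)
            if n < 3:
                raise ValidationError(
                    f"region {region!r}: need n >= 3 paired observations, "
                    f"got {n}"
                )
            x = merged["marker"].to_numpy(dtype=float)
            y = merged[self.value_col].to_numpy(dtype=float)
            res = sps.linregress(x, y)
            p = res.pvalue
            if not np.isfinite(p) or p <= 0:
                p = MIN_P  # perfect fit: below machine resolution
            rows.append({
                "region": region,
                "slope": res.slope,
                "intercept": res.intercept,
                "r": res.rvalue,
                "p": p,
                "n": n,
            })
        table = pd.DataFrame(rows).sort_values("region").reset_index(drop=True)
        table["lobe"] = _region_lobes(table["region"], self.lobe_map)
        table["q"], table["significant"] = grouped_bh_fdr(
            table["p"].to_numpy(), table["lobe"].to_numpy(), self.alpha
        )
        return MarkerRegressionResults(self, table)


class MarkerRegressionResults:
    """Fitted per-region regressions; the heatmap-with-asterisks analogue."""

    def __init__(self, model: MarkerRegression, table: pd.DataFrame):
        self.model = model
        self.table = table

    def summary(self) -> str:
        sig = self.table["significant"]
        lines = [
            f"Per-region marker regression "
            f"(within-lobe BH-FDR alpha={self.model.alpha:g})",
            f"  regions: {len(self.table)}   "
            f"passing FDR: {int(sig.sum())}",
        ]
        for row in self.table[sig].itertuples(index=False):
            lines.append(
                f"    {row.region} ({row.lobe}): slope={row.slope:.4g} "
                f"r={row.r:.3f} q={row.q:.3g}"
            )
        return "\n".join(lines)


def regress_marker(values: pd.DataFrame, marker, lobe_map,
                   alpha: float = 0.05, **kwargs) -> pd.DataFrame:
    """Functional wrapper over ``MarkerRegression``; returns the table."""
    return MarkerRegression(values, marker, lobe_map, alpha, **kwargs).fit().table


def delta_interaction_by_region(values: pd.DataFrame, arm_col: str = "arm",
                                time_col: str = "pre_post",
                                alpha: float = 0.05,
                                value_col: str = "value",
                                region_col: str = "region") -> pd.DataFrame:
    """Per-region treatment-by-time interaction on paired pre/post values.

    For each region the per-subject change (post - pre) is computed within
    each arm and the arms are compared with the pooled-t interaction test;
    mean change per arm is reported alongside p.  Arms are ordered
    lexicographically (first = A).
    """
    arms = sorted(values[arm_col].unique())
    if len(arms) != 2:
        raise ValidationError(f"expected exactly 2 arms, got {arms}")
    times = set(values[time_col].unique())
    if times != {"pre", "post"}:
        raise ValidationError(
            f"{time_col} must contain exactly 'pre' and 'post', got {sorted(times)}"
        )
    rows = []
    for region, sub in values.groupby(region_col):
        deltas = {}
        for arm in arms:
            arm_df = sub[sub[arm_col] == arm]
            pre = arm_df[arm_df[time_col] == "pre"].set_index(
                "subject_id")[value_col]
            post = arm_df[arm_df[time_col] == "post"].set_index(
                "subject_id")[value_col]
            unpaired = sorted(set(pre.index) ^ set(post.index))
            if unpaired:
                raise ValidationError(
                    f"region {region!r}, arm {arm!r}: unpaired subject(s) "
                    f"{unpaired}"
                )
            deltas[arm] = (post - pre).sort_index().to_numpy()
        p = interaction_delta_test(deltas[arms[0]], deltas[arms[1]])
        rows.append({
            "region": region,
            f"mean_delta_{arms[0]}": deltas[arms[0]].mean(),
            f"mean_delta_{arms[1]}": deltas[arms[1]].mean(),
            "p_interaction": p,
            "significant": p < alpha,
        })
    return pd.DataFrame(rows).sort_values("region").reset_index(drop=True)
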