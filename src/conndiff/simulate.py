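"""Synthetic cohort generator with known connectivity ground truth.

Cohorts of parcellated "BOLD-like" time series are drawn from stationary
Gaussian processes with designed contemporaneous correlation matrices, so
every downstream stage (FC estimation, edge-wise contrasts, FDR,
classification, aggregation) can be exercised and validated against a
known answer without any imaging data.

Group differences are injected on the Fisher-z scale — the scale on which
edge effects are tested — and mapped back through tanh, so an injection of
``delta_z = 0.5`` at an edge is exactly the effect size the contrast layer
should recover.  Temporal smoothness of band-limited resting-state signal
is emulated by an AR(1) innovation-sharing scheme whose contemporaneous
correlation equals the target matrix regardless of the AR coefficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .fc import BoldTimeSeries, Edge, edge_index, write_time_series
from .regions import (
    HEMISPHERES,
    LOBES,
    NETWORKS,
    RegionMeta,
    write_region_meta,
)

#: eigenvalue floor used when repairing indefinite correlation matrices
EIG_FLOOR = 1e-6

#: maximum tolerated distortion of an injected effect after repair
INJECTION_TOL = 1e-3


@dataclass(frozen=True)
class EdgeEffect:
    """Target Fisher-z difference (condition A minus B) at one edge."""

    edge: Edge
    delta_z: float


@dataclass
class CrossSectionalArms:
    """Two independent groups compared at a single timepoint."""

    n_a: int = 56   # insulin-resistant group size in the source cohort
    n_b: int = 18   # healthy-control group size

    kind: str = field(default="cross_sectional", init=False)

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ValidationError("need at least 2 subjects per group")


@dataclass
class RctArms:
    """Two-arm randomized trial with paired pre/post scans per subject."""

    n_per_arm: int = 20

    kind: str = field(default="rct", init=False)

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValidationError("need at least 2 subjects per arm")


@dataclass
class SyntheticDesign:
    """Full generative specification of a synthetic cohort.

    Parameters
    ----------
    meta : list of RegionMeta
        Parcellation; defaults to 32 regions spread over all lobes,
        networks and hemispheres (see ``make_parcellation``).
    base_z : float or ndarray
        Background connectivity: a common Fisher-z level for every edge
        (scalar) or a full base correlation matrix.
    injections : list of EdgeEffect
        Edge-level Fisher-z effects carried by condition A (the second
        group in cross-sectional mode; the treated arm's post scans in
        RCT mode).
    arms : CrossSectionalArms or RctArms
    n_timepoints : int
        Scan length (default 116 volumes).
    tr_seconds : float
        Repetition time (default 3.0 s).
    ar_coef : float
        AR(1) temporal smoothness in [0, 0.95); 0 gives white noise.
    noise_sd : float
        Overall signal scale (does not affect correlations).
    seed : int
        Master seed; every subject's stream is derived from it.
    """

    meta: list[RegionMeta] | None = None
    base_z: float | np.ndarray = 0.1
    injections: list[EdgeEffect] = field(default_factory=list)
    arms: CrossSectionalArms | RctArms = field(
        default_factory=CrossSectionalArms)
    n_timepoints: int = 116
    tr_seconds: float = 3.0
    ar_coef: float = 0.4
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.meta is None:
            self.meta = make_parcellation(32, seed=self.seed)
        if self.n_timepoints < 3:
            raise ValidationError("n_timepoints must be >= 3")
        if not (0 <= self.ar_coef < 0.95 + 1e-12):
            raise ValidationError("ar_coef must be in [0, 0.95]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        n = len(self.meta)
        for eff in self.injections:
            if eff.edge.j >= n:
                raise ValidationError(
                    f"injection edge ({eff.edge.i}, {eff.edge.j}) out of "
                    f"range for {n} regions"
                )

    @property
    def n_regions(self) -> int:
        return len(self.meta)


@dataclass
class GroundTruth:
    """Injected effects and the realized per-condition correlation matrices."""

    injections: list[EdgeEffect]
    cov_a: np.ndarray
    cov_b: np.ndarray

    def injected_indices(self) -> np.ndarray:
        n = self.cov_a.shape[0]
        return np.array(
            [edge_index(e.edge.i, e.edge.j, n) for e in self.injections],
            dtype=int,
        )

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "injections": [
                {"i": e.edge.i, "j": e.edge.j, "delta_z": e.delta_z}
                for e in self.injections
            ],
        }
        (out_dir / "ground_truth.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        for name, m in (("cov_a", self.cov_a), ("cov_b", self.cov_b)):
            pd.DataFrame(m).to_csv(
                out_dir / f"{name}.tsv", sep="\t", index=False,
                header=False, float_format="%.12g",
            )


def make_parcellation(n_regions: int, seed: int = 0) -> list[RegionMeta]:
    """Seeded synthetic parcellation covering the full label vocabulary.

    Lobes, networks and hemispheres are assigned round-robin (so counts
    per label are as even as possible) and then shuffled across region ids
    with the given seed.  Requires at least 8 regions so every lobe is
    represented.
    """
    if n_regions < 8:
        raise ValidationError(
            f"need at least 8 regions to cover all lobes, got {n_regions}"
        )
    combos = [
        (LOBES[k % len(LOBES)], NETWORKS[k % len(NETWORKS)],
         HEMISPHERES[k % len(HEMISPHERES)])
        for k in range(n_regions)
    ]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    perm = rng.permutation(n_regions)
    regions = []
    for rid in range(n_regions):
        lobe, network, hemi = combos[perm[rid]]
        regions.append(RegionMeta(
            region_id=rid,
            name=f"{hemi[0]}_{lobe}_{network.replace(' ', '')}_{rid:03d}",
            hemisphere=hemi, lobe=lobe, network=network,
        ))
    return regions


def base_correlation(base_z, n_regions: int) -> np.ndarray:
    """Base correlation matrix from a scalar z level or a full matrix."""
    if np.isscalar(base_z):
        r = float(np.tanh(base_z))
        m = np.full((n_regions, n_regions), r)
        np.fill_diagonal(m, 1.0)
        return m
    m = np.asarray(base_z, dtype=float)
    if m.shape != (n_regions, n_regions):
        raise ValidationError(
            f"base correlation matrix shape {m.shape} != "
            f"({n_regions}, {n_regions})"
        )
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValidationError("base correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0):
        raise ValidationError("base correlation matrix must have unit diagonal")
    off = m[~np.eye(n_regions, dtype=bool)]
    if np.any(np.abs(off) >= 1):
        raise ValidationError("base correlations must be in (-1, 1)")
    return m.copy()


def nearest_positive_definite(m: np.ndarray,
                              eig_floor: float = EIG_FLOOR) -> np.ndarray:
    """Repair a symmetric matrix to a unit-diagonal positive-definite one.

    Already-PD unit-diagonal input is returned unchanged; otherwise
    eigenvalues are clipped at ``eig_floor``, the matrix reconstructed and
    the diagonal renormalized to 1.  The result is verified by Cholesky.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValidationError("matrix must be symmetric")
    if np.allclose(np.diag(m), 1.0):
        try:
            np.linalg.cholesky(m)
            return m.copy()
        except np.linalg.LinAlgError:
            pass
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    w = np.maximum(w, eig_floor)
    a = (v * w) @ v.T
    d = 1.0 / np.sqrt(np.diag(a))
    a = a * np.outer(d, d)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    np.linalg.cholesky(a)  # raises if the repair failed
    return a


def build_group_covariance(base_z, injections: Sequence[EdgeEffect],
                           condition: str, n_regions: int) -> np.ndarray:
    """Condition correlation matrix realizing the injected z effects.

    Condition "B" is the base; condition "A" carries each injection as a
    Fisher-z shift at its edge, mapped back through tanh.  Both matrices
    are repaired to positive definite if needed, and the realized z gap at
    every injected edge is re-checked against its target to within 1e-3
    (otherwise an error advises smaller effects or sparser injections).
    """
    if condition not in ("A", "B"):
        raise ValidationError(f"condition must be 'A' or 'B', got {condition!r}")
    cov_a, cov_b = condition_matrices(base_z, injections, n_regions)
    return cov_a if condition == "A" else cov_b


def condition_matrices(base_z, injections: Sequence[EdgeEffect],
                       n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Repaired (A, B) correlation matrices with verified injected deltas."""
    rb = base_correlation(base_z, n_regions)
    ra = rb.copy()
    for eff in injections:
        i, j = eff.edge.i, eff.edge.j
        if j >= n_regions:
            raise ValidationError(
                f"injection edge ({i}, {j}) out of range for R={n_regions}"
            )
        z_new = np.arctanh(rb[i, j]) + eff.delta_z
        r_new = np.tanh(z_new)
        ra[i, j] = ra[j, i] = r_new
    cov_b = nearest_positive_definite(rb)
    cov_a = nearest_positive_definite(ra)
    for eff in injections:
        i, j = eff.edge.i, eff.edge.j
        realized = np.arctanh(cov_a[i, j]) - np.arctanh(cov_b[i, j])
        if abs(realized - eff.delta_z) > INJECTION_TOL:
            raise ValidationError(
                f"positive-definite repair distorted injected edge "
                f"({i}, {j}): realized delta_z {realized:.6f} vs target "
                f"{eff.delta_z:.6f}; use smaller effects or sparser injections"
            )
    return cov_a, cov_b


def simulate_subject(cov: np.ndarray, n_timepoints: int, ar_coef: float,
                     noise_sd: float, seed,
                     subject_id: str = "sub",
                     tr_seconds: float = 3.0,
                     region_names: Sequence[str] | None = None
                     ) -> BoldTimeSeries:
    """Stationary Gaussian series with contemporaneous correlation ``cov``.

    ``x_t = phi * x_{t-1} + sqrt(1 - phi^2) * L eps_t`` with L the Cholesky
    factor of ``cov`` and a stationary start, so the marginal correlation
    matrix equals ``cov`` at every t for any phi in [0, 1).
    """
    cov = np.asarray(cov, dtype=float)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "covariance is not positive definite; repair it first"
        ) from exc
    if not (0 <= ar_coef < 1):
        raise ValidationError("ar_coef must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = cov.shape[0]
    eps = rng.standard_normal((n_timepoints, n))
    innov = eps @ chol.T
    if ar_coef == 0:
        x = innov
    else:
        x = np.empty_like(innov)
        x[0] = innov[0]
        scale = np.sqrt(1.0 - ar_coef ** 2)
        for t in range(1, n_timepoints):
            x[t] = ar_coef * x[t - 1] + scale * innov[t]
    return BoldTimeSeries(
        subject_id=subject_id,
        values=noise_sd * x,
        tr_seconds=tr_seconds,
        region_names=list(region_names) if region_names is not None else None,
    )


def _subject_seed(master_seed: int, subject_index: int, time_code: int):
    """Deterministic per-subject, per-scan seed stream."""
    return np.random.SeedSequence(
        [int(master_seed), int(subject_index), int(time_code)]
    )


@dataclass
class Cohort:
    """Simulated cohort: the design, its ground truth, and all series.

    ``groups`` maps condition labels to subject series lists — keys "A"/"B"
    for cross-sectional designs, "treated_pre"/"treated_post"/
    "control_pre"/"control_post" for RCT designs.
    """

    design: SyntheticDesign
    ground_truth: GroundTruth
    groups: dict[str, list[BoldTimeSeries]]

    def write(self, out_dir: str | Path) -> None:
        """Dump region metadata, per-subject TSVs, and the ground truth."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_region_meta(self.design.meta, out_dir / "regions.tsv")
        for label, series in self.groups.items():
            gdir = out_dir / label
            gdir.mkdir(exist_ok=True)
            for ts in series:
                write_time_series(ts, gdir / f"{ts.subject_id}.tsv")
        self.ground_truth.save(out_dir / "truth")


def simulate_cohort(design: SyntheticDesign,
                    master_seed: int | None = None) -> Cohort:
    """Generate a full cohort from a design; fully reproducible by seed.

    Cross-sectional mode draws ``n_a`` subjects from the A (effect-carrying)
    matrix and ``n_b`` from B.  RCT mode draws paired pre/post scans per
    subject in each arm: all pre scans and the control arm's post scans come
    from the base matrix; treated post scans carry the injected effects.
    Each scan has its own seed derived from the master seed, so cohorts are
    regenerable subject by subject.
    """
    seed = design.seed if master_seed is None else int(master_seed)
    cov_a, cov_b = condition_matrices(
        design.base_z, design.injections, design.n_regions
    )
    truth = GroundTruth(
        injections=list(design.injections), cov_a=cov_a, cov_b=cov_b
    )
    names = [r.name for r in design.meta]

    def draw(cov, sid, subj_idx, time_code):
        return simulate_subject(
            cov, design.n_timepoints, design.ar_coef, design.noise_sd,
            seed=_subject_seed(seed, subj_idx, time_code),
            subject_id=sid, tr_seconds=design.tr_seconds, region_names=names,
        )

    groups: dict[str, list[BoldTimeSeries]] = {}
    if design.arms.kind == "cross_sectional":
        groups["A"] = [
            draw(cov_a, f"A{k + 1:03d}", k, 0)
            for k in range(design.arms.n_a)
        ]
        groups["B"] = [
            draw(cov_b, f"B{k + 1:03d}", design.arms.n_a + k, 0)
            for k in range(design.arms.n_b)
        ]
    else:
        n = design.arms.n_per_arm
        groups["treated_pre"] = [
            draw(cov_b, f"met{k + 1:03d}", k, 0) for k in range(n)
        ]
        groups["treated_post"] = [
            draw(cov_a, f"met{k + 1:03d}", k, 1) for k in range(n)
        ]
        groups["control_pre"] = [
            draw(cov_b, f"pla{k + 1:03d}", n + k, 0) for k in range(n)
        ]
        groups["control_post"] = [
            draw(cov_b, f"pla{k + 1:03d}", n + k, 1) for k in range(n)
        ]
    return Cohort(design=design, ground_truth=truth, groups=groups)


# -------------------------------------------------------------------------
# Design (de)serialization
# -------------------------------------------------------------------------

def design_to_dict(design: SyntheticDesign) -> dict:
    d = {
        "n_regions": design.n_regions,
        "base_z": (
            float(design.base_z) if np.isscalar(design.base_z)
            else np.asarray(design.base_z).tolist()
        ),
        "injections": [
            {"i": e.edge.i, "j": e.edge.j, "delta_z": e.delta_z}
            for e in design.injections
        ],
        "arms": (
            {"kind": "cross_sectional", "n_a": design.arms.n_a,
             "n_b": design.arms.n_b}
            if design.arms.kind == "cross_sectional"
            else {"kind": "rct", "n_per_arm": design.arms.n_per_arm}
        ),
        "n_timepoints": design.n_timepoints,
        "tr_seconds": design.tr_seconds,
        "ar_coef": design.ar_coef,
        "noise_sd": design.noise_sd,
        "seed": design.seed,
    }
    return d


def design_from_dict(d: dict) -> SyntheticDesign:
    arms_d = d.get("arms", {"kind": "cross_sectional"})
    if arms_d.get("kind") == "rct":
        arms = RctArms(n_per_arm=int(arms_d.get("n_per_arm", 20)))
    else:
        arms = CrossSectionalArms(
            n_a=int(arms_d.get("n_a", 56)), n_b=int(arms_d.get("n_b", 18))
        )
    base_z = d.get("base_z", 0.1)
    if isinstance(base_z, list):
        base_z = np.asarray(base_z, dtype=float)
    seed = int(d.get("seed", 0))
    meta = make_parcellation(int(d.get("n_regions", 32)), seed=seed)
    return SyntheticDesign(
        meta=meta,
        base_z=base_z,
        injections=[
            EdgeEffect(Edge(int(e["i"]), int(e["j"])), float(e["delta_z"]))
            for e in d.get("injections", [])
        ],
        arms=arms,
        n_timepoints=int(d.get("n_timepoints", 116)),
        tr_seconds=float(d.get("tr_seconds", 3.0)),
        ar_coef=float(d.get("ar_coef", 0.4)),
        noise_sd=float(d.get("noise_sd", 1.0)),
        seed=seed,
    )


def read_design(path: str | Path) -> SyntheticDesign:
    """Read a design from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


def write_design(design: SyntheticDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=True)
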