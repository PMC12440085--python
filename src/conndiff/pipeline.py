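"""End-to-end pipeline drivers and run manifests.

Two entry points mirror the two study designs: ``run_cross_sectional``
(two groups compared at baseline) and ``run_rct`` (placebo-subtracted
treatment effect on paired pre/post scans).  Each run writes its tables
plus a ``manifest.json`` recording the configuration hash, master seed,
package version, input digests and stage row counts, sufficient to
regenerate every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    aggregate_pairs,
    classify_contrast,
    classify_longitudinal_table,
    count_categories,
    export_chord_table,
    hub_table,
)
from .contrast import EdgewiseContrast, TreatmentContrast
from .exceptions import ConfigError, ValidationError
from .fc import compute_fc_matrix, read_time_series
from .regions import labels_for, read_region_meta
from .stats import TEST_CHOICES, WEIGHT_SCHEMES, _check_alpha

logger = logging.getLogger(__name__)

AGGREGATION_LEVELS = ("hemisphere", "lobe", "network")


@dataclass
class PipelineConfig:
    """Validated configuration for a pipeline run.

    ``paths`` holds the filesystem layout: always ``region_meta`` and
    ``out_dir``; plus ``group_a``/``group_b`` time-series directories for
    the cross-sectional pipeline, or ``treated_pre``/``treated_post``/
    ``control_pre``/``control_post`` for the RCT pipeline.
    """

    paths: dict = field(default_factory=dict)
    alpha: float = 0.05
    threshold: float = 0.05
    test: str = "student"
    fdr_family: str = "all_edges"
    weight_scheme: str = "one_minus_q"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        _check_alpha(self.alpha)
        if self.threshold <= 0:
            raise ConfigError(
                f"threshold must be positive, got {self.threshold}"
            )
        if self.test not in TEST_CHOICES:
            raise ConfigError(f"unknown test {self.test!r}")
        if self.weight_scheme not in WEIGHT_SCHEMES:
            raise ConfigError(f"unknown weight scheme {self.weight_scheme!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "paths": {k: str(v) for k, v in self.paths.items()},
            "alpha": self.alpha,
            "threshold": self.threshold,
            "test": self.test,
            "fdr_family": self.fdr_family,
            "weight_scheme": self.weight_scheme,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def require_paths(self, keys: tuple[str, ...]) -> None:
        missing = [k for k in keys if k not in self.paths]
        if missing:
            raise ConfigError(f"config paths missing {missing}")
        for k in keys:
            if k == "out_dir":
                continue
            if not Path(self.paths[k]).exists():
                raise ValidationError(
                    f"config path {k!r} does not exist: {self.paths[k]}"
                )


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_group(dir_path: str | Path):
    """Read all per-subject time-series TSVs in a directory, sorted."""
    files = sorted(Path(dir_path).glob("*.tsv"))
    if not files:
        raise ValidationError(f"no .tsv time-series files in {dir_path}")
    digests = {f.name: _sha256_file(f) for f in files}
    series = [read_time_series(f) for f in files]
    return series, digests


def _fc_stage(series, stage: str):
    t0 = time.perf_counter()
    fcs = [compute_fc_matrix(ts) for ts in series]
    logger.info("stage=%s n_subjects=%d elapsed=%.2fs",
                stage, len(fcs), time.perf_counter() - t0)
    return fcs


def _write_manifest(out_dir: Path, config: PipelineConfig, digests: dict,
                    counts: dict) -> Path:
    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "input_digests": dict(sorted(digests.items())),
        "counts": counts,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _export_aggregates(classified: pd.DataFrame, meta, out_dir: Path,
                       prefix: str = "") -> dict:
    counts = {}
    for level in AGGREGATION_LEVELS:
        table = aggregate_pairs(classified, meta, level)
        export_chord_table(table, out_dir / f"{prefix}chord_{level}.tsv")
        counts[f"{prefix}pairs_{level}"] = table.total_edges
    hubs = hub_table(classified, meta)
    hubs.to_csv(out_dir / f"{prefix}hub.tsv", sep="\t", index=False,
                float_format="%.10g")
    counts[f"{prefix}hub_regions"] = len(hubs)
    return counts


def run_cross_sectional(config: PipelineConfig) -> dict:
    """Two-group baseline comparison: FC -> contrast -> classify -> tables.

    Group A is the first condition of the contrast (delta_z = A - B; in
    the motivating design A is the insulin-resistant group and B the
    healthy controls).  Returns a dict of output paths.
    """
    config.require_paths(("region_meta", "group_a", "group_b", "out_dir"))
    out_dir = Path(config.paths["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = read_region_meta(config.paths["region_meta"])
    lobes = labels_for(meta, "lobe")

    series_a, dig_a = _load_group(config.paths["group_a"])
    series_b, dig_b = _load_group(config.paths["group_b"])
    digests = {f"group_a/{k}": v for k, v in dig_a.items()}
    digests.update({f"group_b/{k}": v for k, v in dig_b.items()})
    digests["region_meta"] = _sha256_file(Path(config.paths["region_meta"]))

    fc_a = _fc_stage(series_a, "fc_group_a")
    fc_b = _fc_stage(series_b, "fc_group_b")

    results = EdgewiseContrast(
        fc_a, fc_b, alpha=config.alpha, test=config.test,
        weight_scheme=config.weight_scheme, fdr_family=config.fdr_family,
        region_lobes=lobes, kind="cross_sectional",
    ).fit()
    logger.info("stage=contrast n_edges=%d n_significant=%d",
                results.n_edges, results.n_significant)
    results.save_tsv(out_dir / "contrast.tsv")

    classified = classify_contrast(results, threshold=config.threshold,
                                   meta=meta)
    classified.to_csv(out_dir / "classified.tsv", sep="\t", index=False,
                      float_format="%.10g")
    tally = count_categories(classified["category"])
    tally.to_csv(out_dir / "category_tally.tsv", sep="\t", index=False,
                 float_format="%.10g")
    logger.info("stage=classify n_classified=%d", len(classified))

    counts = {
        "n_edges": results.n_edges,
        "n_significant": results.n_significant,
        "tally": {
            str(r.category): int(r.count) for r in tally.itertuples(index=False)
        },
    }
    counts.update(_export_aggregates(classified, meta, out_dir))
    _write_manifest(out_dir, config, digests, counts)
    return {
        "contrast": out_dir / "contrast.tsv",
        "classified": out_dir / "classified.tsv",
        "tally": out_dir / "category_tally.tsv",
        "hub": out_dir / "hub.tsv",
        "manifest": out_dir / "manifest.json",
        "out_dir": out_dir,
        "results": results,
    }


def run_rct(config: PipelineConfig) -> dict:
    """Placebo-subtracted treatment effect on paired pre/post scans.

    delta_z > 0 means a greater connectivity increase in the treated arm.
    Treatment-significant edges are classified longitudinally within each
    arm using that arm's pre/post edge means, giving the four-bar tallies
    (more/less positive, more/less negative) per arm.
    """
    config.require_paths((
        "region_meta", "treated_pre", "treated_post",
        "control_pre", "control_post", "out_dir",
    ))
    out_dir = Path(config.paths["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = read_region_meta(config.paths["region_meta"])
    lobes = labels_for(meta, "lobe")

    loaded = {}
    digests = {"region_meta": _sha256_file(Path(config.paths["region_meta"]))}
    for key in ("treated_pre", "treated_post", "control_pre", "control_post"):
        series, dig = _load_group(config.paths[key])
        loaded[key] = _fc_stage(series, f"fc_{key}")
        digests.update({f"{key}/{k}": v for k, v in dig.items()})

    model = TreatmentContrast(
        loaded["treated_pre"], loaded["treated_post"],
        loaded["control_pre"], loaded["control_post"],
        alpha=config.alpha, test=config.test,
        weight_scheme=config.weight_scheme, fdr_family=config.fdr_family,
        region_lobes=lobes,
    )
    results = model.fit()
    logger.info("stage=treatment_contrast n_edges=%d n_significant=%d",
                results.n_edges, results.n_significant)
    results.save_tsv(out_dir / "contrast.tsv")

    counts = {
        "n_edges": results.n_edges,
        "n_significant": results.n_significant,
    }
    for arm, pre_key, post_key in (
        ("treated", "treated_pre", "treated_post"),
        ("control", "control_pre", "control_post"),
    ):
        mean_pre = np.vstack(
            [m.edge_values() for m in loaded[pre_key]]).mean(axis=0)
        mean_post = np.vstack(
            [m.edge_values() for m in loaded[post_key]]).mean(axis=0)
        classified = classify_longitudinal_table(
            results, mean_pre, mean_post,
            threshold=config.threshold, meta=meta,
        )
        classified.to_csv(out_dir / f"classified_{arm}.tsv", sep="\t",
                          index=False, float_format="%.10g")
        tally = count_categories(classified["category"])
        tally.to_csv(out_dir / f"category_tally_{arm}.tsv", sep="\t",
                     index=False, float_format="%.10g")
        counts[f"tally_{arm}"] = {
            str(r.category): int(r.count) for r in tally.itertuples(index=False)
        }
        counts.update(
            _export_aggregates(classified, meta, out_dir, prefix=f"{arm}_")
        )
    _write_manifest(out_dir, config, digests, counts)
    return {
        "contrast": out_dir / "contrast.tsv",
        "classified_treated": out_dir / "classified_treated.tsv",
        "classified_control": out_dir / "classified_control.tsv",
        "manifest": out_dir / "manifest.json",
        "out_dir": out_dir,
        "results": results,
    }
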