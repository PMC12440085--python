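"""Brain parcellation metadata.

A parcellation is a list of regions, each tagged with a hemisphere, an
anatomical division ("lobe") and a resting-state functional network.  The
label vocabularies are fixed: eight lobes and nine networks, the grouping
levels at which significant connections are aggregated downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ValidationError

HEMISPHERES: tuple[str, ...] = ("Left", "Right")

LOBES: tuple[str, ...] = (
    "Frontal",
    "Temporal",
    "Parietal",
    "Occipital",
    "Limbic",
    "Cerebellum",
    "Subcortical",
    "Insular",
)

NETWORKS: tuple[str, ...] = (
    "Auditory",
    "Cerebellar",
    "Default Mode",
    "Dorsal Attention",
    "Executive Control",
    "Salience",
    "Sensorimotor",
    "Subcortical",
    "Visual",
)

_META_COLUMNS = ("region_id", "name", "hemisphere", "lobe", "network")


@dataclass(frozen=True)
class RegionMeta:
    """One parcel: integer id, free-text name, and its three labels."""

    region_id: int
    name: str
    hemisphere: str
    lobe: str
    network: str

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"region {self.region_id} ({self.name!r}): unknown hemisphere "
                f"{self.hemisphere!r}; expected one of {HEMISPHERES}"
            )
        if self.lobe not in LOBES:
            raise ValidationError(
                f"region {self.region_id} ({self.name!r}): unknown lobe "
                f"{self.lobe!r}; expected one of {LOBES}"
            )
        if self.network not in NETWORKS:
            raise ValidationError(
                f"region {self.region_id} ({self.name!r}): unknown network "
                f"{self.network!r}; expected one of {NETWORKS}"
            )


def validate_regions(regions: Sequence[RegionMeta]) -> list[RegionMeta]:
    """Check id uniqueness/contiguity and return regions sorted by id."""
    ordered = sorted(regions, key=lambda r: r.region_id)
    ids = [r.region_id for r in ordered]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate region_id(s): {dupes}")
    if ids != list(range(len(ids))):
        raise ValidationError(
            f"region_ids must be contiguous 0..{len(ids) - 1}; got {ids}"
        )
    return list(ordered)


def regions_to_frame(regions: Sequence[RegionMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.region_id, r.name, r.hemisphere, r.lobe, r.network)
            for r in regions
        ],
        columns=list(_META_COLUMNS),
    )


def read_region_meta(path: str | Path) -> list[RegionMeta]:
    """Read a parcellation table (TSV with the five required columns).

    Labels outside the fixed vocabularies are rejected with the offending
    row number (1-based, excluding the header) quoted in the message.
    """
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    regions = []
    for pos, row in enumerate(df.itertuples(index=False), start=1):
        try:
            regions.append(
                RegionMeta(
                    region_id=int(row.region_id),
                    name=str(row.name),
                    hemisphere=str(row.hemisphere),
                    lobe=str(row.lobe),
                    network=str(row.network),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {pos}: {exc}") from exc
    return validate_regions(regions)


def write_region_meta(regions: Iterable[RegionMeta], path: str | Path) -> None:
    regions_to_frame(validate_regions(list(regions))).to_csv(
        path, sep="\t", index=False
    )


def labels_for(regions: Sequence[RegionMeta], level: str) -> list[str]:
    """Per-region label vector at a grouping level.

    ``level`` is one of ``hemisphere``, ``lobe``, ``network``.
    """
    if level not in ("hemisphere", "lobe", "network"):
        raise ValidationError(
            f"unknown aggregation level {level!r}; "
            "expected hemisphere, lobe or network"
        )
    return [getattr(r, level) for r in validate_regions(list(regions))]


def level_vocabulary(level: str) -> tuple[str, ...]:
    return {
        "hemisphere": HEMISPHERES,
        "lobe": LOBES,
        "network": NETWORKS,
    }[level]
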