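"""Differential-expression screening and candidate-protein prioritization.

Two gates are applied, mirroring the discovery workflow: an ion-level
fold-change screen (tumor/control ratio strictly above the threshold,
default 4x), then protein-level prioritization — a candidate must be
supported by more than one distinct differential peptide, observed in more
than one malignant sample, show a median ratio above the threshold, and be
annotated as secreted or cell-membrane localized.

When a control intensity falls below the detection floor, the ratio is a
*censored lower bound* (tumor intensity over the floor); censored records
pass the screen only if the bound itself exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import FeatureMatrix
from .synth import IonMap

__all__ = [
    "DiscoveryConfig",
    "PairAssignment",
    "infer_pairs",
    "compute_peptide_ratios",
    "flag_differential_peptides",
    "aggregate_to_protein",
    "apply_prioritization_filters",
]


@dataclass
class DiscoveryConfig:
    ratio_threshold: float = 4.0        # strict >
    min_peptides: int = 2               # "multiple" read as >= 2
    min_samples: int = 2
    allowed_localizations: tuple[str, ...] = ("secreted", "cell_membrane")
    detection_floor: float = 2.0 ** 16

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be positive")
        if self.min_peptides < 1 or self.min_samples < 1:
            raise ValueError("minimum counts must be >= 1")


@dataclass
class PairAssignment:
    pair_id: str
    tumor_map_id: str
    control_map_id: str
    platform: str


class MissingPairError(ValueError):
    """A tumor map has no designated control."""


def infer_pairs(maps: list[IonMap]) -> list[PairAssignment]:
    """Derive tumor/control pair assignments from map metadata."""
    by_id = {m.map_id: m for m in maps}
    pairs = []
    for m in sorted(maps, key=lambda m: m.map_id):
        if m.condition != "tumor":
            continue
        if not m.paired_map_id or m.paired_map_id not in by_id:
            raise MissingPairError(f"tumor map {m.map_id} has no paired control map")
        pairs.append(
            PairAssignment(
                pair_id=f"{m.map_id}|{m.paired_map_id}",
                tumor_map_id=m.map_id,
                control_map_id=m.paired_map_id,
                platform=m.platform,
            )
        )
    return pairs


def compute_peptide_ratios(
    fm: FeatureMatrix,
    pairs: list[PairAssignment],
    detection_floor: float | None = None,
) -> pd.DataFrame:
    """Tumor/control fold change per identified feature per sample pair.

    Ratios are computed on normalized log2 intensities as
    ``2**(tumor - control)``. A missing control yields a censored lower
    bound: the tumor intensity divided by the detection floor expressed on
    the control map's normalized scale. A missing tumor yields no record.
    Internal standards and unidentified features are skipped.
    """
    if detection_floor is None:
        detection_floor = 2.0 ** 16
    meta = fm.meta
    informative = (~meta["is_internal_standard"].astype(bool)) & (meta["peptide"] != "")
    rows = []
    for pair in pairs:
        for col in (pair.tumor_map_id, pair.control_map_id):
            if col not in fm.data.columns:
                raise MissingPairError(f"map {col} absent from feature matrix")
        t = fm.data[pair.tumor_map_id]
        c = fm.data[pair.control_map_id]
        floor_log2 = np.log2(detection_floor) + float(fm.offsets[pair.control_map_id])
        for gid in fm.data.index[informative.to_numpy()]:
            tv, cv = t.at[gid], c.at[gid]
            if pd.isna(tv):
                continue
            if pd.isna(cv):
                ratio, censored = 2.0 ** (tv - floor_log2), True
            else:
                ratio, censored = 2.0 ** (tv - cv), False
            rows.append(
                (
                    meta.at[gid, "peptide"],
                    meta.at[gid, "protein"],
                    pair.pair_id,
                    pair.platform,
                    gid,
                    float(ratio),
                    censored,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["peptide", "protein", "pair_id", "platform", "group_id", "ratio", "censored"],
    )


def flag_differential_peptides(
    ratios: pd.DataFrame, config: DiscoveryConfig | None = None
) -> pd.DataFrame:
    """Retain records whose ratio (or censored lower bound) strictly exceeds the threshold."""
    config = config or DiscoveryConfig()
    return ratios[ratios["ratio"] > config.ratio_threshold].reset_index(drop=True)


def aggregate_to_protein(
    flagged: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Protein-level candidate table from flagged differential peptides.

    Per accession: distinct differential peptides, distinct sample pairs,
    the median of all flagged peptide ratios (censored bounds enter at their
    bound), and the platform membership set. Localization comes from the
    annotation table; unknown accessions fall back to "other" with a warning.
    """
    loc_map = dict(zip(annotations["accession"], annotations["localization"]))
    if flagged.empty:
        return pd.DataFrame(
            columns=[
                "accession", "localization", "n_peptides", "n_samples",
                "median_ratio", "platforms", "peptides",
            ]
        )
    rows = []
    missing = []
    for accession, sub in flagged.groupby("protein", sort=True):
        if accession not in loc_map:
            missing.append(accession)
        rows.append(
            {
                "accession": accession,
                "localization": loc_map.get(accession, "other"),
                "n_peptides": sub["peptide"].nunique(),
                "n_samples": sub["pair_id"].nunique(),
                "median_ratio": float(sub["ratio"].median()),
                "platforms": ";".join(sorted(sub["platform"].unique())),
                "peptides": ";".join(sorted(sub["peptide"].unique())),
            }
        )
    if missing:
        warnings.warn(
            f"{len(missing)} accession(s) missing from annotations; localization set to 'other'"
        )
    return pd.DataFrame(rows)


def apply_prioritization_filters(
    candidates: pd.DataFrame, config: DiscoveryConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four candidate criteria; returns (retained, audit).

    The audit table carries one boolean per criterion per candidate, so a
    rejected candidate's failing rule is inspectable. The criteria commute:
    retention is their conjunction.
    """
    config = config or DiscoveryConfig()
    audit = candidates.copy()
    audit["pass_peptides"] = audit["n_peptides"] >= config.min_peptides
    audit["pass_samples"] = audit["n_samples"] >= config.min_samples
    audit["pass_ratio"] = audit["median_ratio"] > config.ratio_threshold
    audit["pass_localization"] = audit["localization"].isin(config.allowed_localizations)
    audit["selected"] = (
        audit["pass_peptides"]
        & audit["pass_samples"]
        & audit["pass_ratio"]
        & audit["pass_localization"]
    )
    retained = audit[audit["selected"]].drop(
        columns=["pass_peptides", "pass_samples", "pass_ratio", "pass_localization", "selected"]
    )
    return retained.reset_index(drop=True), audit
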