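"""Multi-platform candidate integration, Venn partitioning and class summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import PLATFORMS

__all__ = [
    "VennPartition",
    "round_half_up_percent",
    "integrate_platforms",
    "venn_partition",
    "summarize_protein_classes",
]


def round_half_up_percent(numerator: float, denominator: float) -> int:
    """Integer percent with exact half-up rounding (no banker's rounding)."""
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def integrate_platforms(
    per_platform_candidates: dict[str, list[str] | pd.DataFrame],
) -> pd.DataFrame:
    """Union candidate accessions over platforms into a membership table.

    Values may be accession lists or candidate tables with an ``accession``
    column. Rows are sorted by accession for deterministic output.
    """
    sets: dict[str, set[str]] = {}
    for platform in PLATFORMS:
        cands = per_platform_candidates.get(platform, [])
        if isinstance(cands, pd.DataFrame):
            cands = cands["accession"].tolist()
        sets[platform] = set(cands)
    union = sorted(set().union(*sets.values()))
    return pd.DataFrame(
        {"accession": union, **{p: [a in sets[p] for a in union] for p in PLATFORMS}}
    )


@dataclass
class VennPartition:
    """Counts of the 7 exclusive regions of a three-set membership."""

    region_counts: dict[tuple[str, ...], int]
    total: int
    per_platform_totals: dict[str, int]

    @property
    def exactly_one(self) -> int:
        return sum(c for r, c in self.region_counts.items() if len(r) == 1)

    @property
    def all_three(self) -> int:
        return self.region_counts.get(tuple(PLATFORMS), 0)

    @property
    def exactly_one_pct(self) -> int:
        return round_half_up_percent(self.exactly_one, self.total)

    @property
    def all_three_pct(self) -> int:
        return round_half_up_percent(self.all_three, self.total)


def venn_partition(membership: pd.DataFrame) -> VennPartition:
    """Exact exclusive region counts of a platform-membership table."""
    if membership.empty:
        return VennPartition(
            region_counts={}, total=0, per_platform_totals={p: 0 for p in PLATFORMS}
        )
    counts: dict[tuple[str, ...], int] = {}
    flags = membership[list(PLATFORMS)].astype(bool).to_numpy()
    if not flags.any(axis=1).all():
        raise ValueError("every marker must belong to at least one platform")
    for row in flags:
        region = tuple(p for p, f in zip(PLATFORMS, row) if f)
        counts[region] = counts.get(region, 0) + 1
    return VennPartition(
        region_counts=counts,
        total=len(membership),
        per_platform_totals={
            p: int(flags[:, i].sum()) for i, p in enumerate(PLATFORMS)
        },
    )


def summarize_protein_classes(
    membership: pd.DataFrame,
    annotations: pd.DataFrame,
    subset: str = "all",
) -> tuple[pd.DataFrame, int]:
    """Protein-class frequency table over a marker subset.

    ``subset`` is ``"all"`` or a platform name (markers identified on that
    platform). Returns (table, coverage_pct) where the table holds per-class
    counts and round-half-up percentages of the *classified* markers, and
    coverage_pct is the percentage of subset markers carrying any class.
    """
    if subset == "all":
        selected = membership
    elif subset in PLATFORMS:
        selected = membership[membership[subset].astype(bool)]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    cls = (
        annotations.set_index("accession")["protein_class"]
        .reindex(selected["accession"])
        .fillna("")
    )
    classified = cls[cls != ""]
    coverage_pct = round_half_up_percent(len(classified), len(selected)) if len(selected) else 0
    counts = classified.value_counts().sort_index()
    table = pd.DataFrame(
        {
            "protein_class": counts.index,
            "count": counts.to_numpy(),
            "pct_of_classified": [
                round_half_up_percent(c, len(classified)) for c in counts.to_numpy()
            ],
        }
    )
    n_unclassified = int((cls == "").sum())
    if n_unclassified:
        table = pd.concat(
            [
                table,
                pd.DataFrame(
                    {
                        "protein_class": ["unclassified"],
                        "count": [n_unclassified],
                        "pct_of_classified": [np.nan],
                    }
                ),
            ],
            ignore_index=True,
        )
    return table, coverage_pct
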