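"""Cross-map alignment of peptide-ion peak lists.

The alignment contract mirrors standard label-free LC/MS practice:

1. a *primary* retention-time normalization per map — an affine warp fitted
   by least squares to spiked internal-standard peptides with known
   reference RTs;
2. a *secondary* fine-tuning — a monotone piecewise-linear correction per
   map fitted to residuals of high-confidence common features against the
   cross-map consensus, iterated until the median absolute residual stops
   improving;
3. grouping of ions across maps on (m/z, warped RT, charge) with one ion
   per map per group, resolving ambiguity by minimum combined distance
   (ppm distance dominating, RT breaking ties);
4. intensity normalization — one additive offset per map on the log2 scale
   minimizing the squared deviation of each observed ion from its
   cross-map mean (an L1/median variant is available), offsets centered to
   sum to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .synth import INTERNAL_STANDARDS, IonMap

__all__ = [
    "AlignmentConfig",
    "RtWarp",
    "MatchResult",
    "NormalizationResult",
    "FeatureMatrix",
    "InsufficientAnchorsError",
    "fit_primary_rt_warp",
    "apply_warp",
    "refine_rt_secondary",
    "match_ions",
    "normalize_intensities",
    "normalization_objective",
    "build_feature_matrix",
]

_BIG = 1e9          # infeasible-assignment sentinel
_RT_TIEBREAK = 1e-3  # weight putting RT distance strictly below ppm distance


class InsufficientAnchorsError(ValueError):
    """Fewer than two internal-standard anchors available for the primary warp."""


@dataclass
class AlignmentConfig:
    mz_tol_ppm: float = 10.0
    rt_tol_min: float = 1.0
    min_maps_for_secondary: int = 2
    normalization: str = "L2_log"       # or "L1_log"
    detection_floor: float = 2.0 ** 16
    n_rt_knots: int = 11
    max_refine_iter: int = 5
    refine_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.mz_tol_ppm <= 0 or self.rt_tol_min <= 0:
            raise ValueError("tolerances must be positive")
        if self.normalization not in ("L2_log", "L1_log"):
            raise ValueError("normalization must be 'L2_log' or 'L1_log'")


@dataclass
class RtWarp:
    """Monotone RT transform for one map (observed -> reference scale)."""

    map_id: str
    kind: str                                   # affine | piecewise_linear
    slope: float = 1.0
    offset: float = 0.0
    knots_obs: np.ndarray | None = None
    knots_ref: np.ndarray | None = None
    anchors: list[tuple[float, float]] = field(default_factory=list)

    def __call__(self, rt: np.ndarray) -> np.ndarray:
        rt = np.asarray(rt, dtype=float)
        if self.kind == "affine":
            return self.slope * rt + self.offset
        xo, xr = self.knots_obs, self.knots_ref
        out = np.interp(rt, xo, xr)
        # linear extension beyond the anchored range using the end segments
        if len(xo) >= 2:
            lo_slope = (xr[1] - xr[0]) / (xo[1] - xo[0])
            hi_slope = (xr[-1] - xr[-2]) / (xo[-1] - xo[-2])
            out = np.where(rt < xo[0], xr[0] + lo_slope * (rt - xo[0]), out)
            out = np.where(rt > xo[-1], xr[-1] + hi_slope * (rt - xo[-1]), out)
        return out


def identity_warp(map_id: str) -> RtWarp:
    return RtWarp(map_id=map_id, kind="affine", slope=1.0, offset=0.0)


def fit_primary_rt_warp(
    ion_map: IonMap, reference_standards: dict[str, float] | None = None
) -> RtWarp:
    """Affine warp minimizing squared residuals over internal-standard anchors."""
    reference_standards = reference_standards or INTERNAL_STANDARDS
    ions = ion_map.ions
    std = ions[ions["is_internal_standard"].astype(bool)]
    obs, ref = [], []
    for _, row in std.iterrows():
        pep = row["peptide"]
        if pep in reference_standards:
            obs.append(float(row["rt_min"]))
            ref.append(float(reference_standards[pep]))
    if len(obs) < 2:
        raise InsufficientAnchorsError(
            f"map {ion_map.map_id}: {len(obs)} internal-standard anchors (need >= 2)"
        )
    slope, offset = np.polyfit(obs, ref, 1)
    if slope <= 0:
        raise ValueError(f"map {ion_map.map_id}: fitted primary warp not increasing")
    return RtWarp(
        map_id=ion_map.map_id,
        kind="affine",
        slope=float(slope),
        offset=float(offset),
        anchors=list(zip(obs, ref)),
    )


def apply_warp(ion_map: IonMap, warp: RtWarp) -> IonMap:
    """Return a copy of the map with retention times transformed by ``warp``."""
    ions = ion_map.ions.copy()
    ions["rt_min"] = warp(ions["rt_min"].to_numpy())
    return IonMap(
        map_id=ion_map.map_id,
        sample_id=ion_map.sample_id,
        condition=ion_map.condition,
        platform=ion_map.platform,
        paired_map_id=ion_map.paired_map_id,
        ions=ions,
    )


# ---------------------------------------------------------------------------
# Secondary refinement
# ---------------------------------------------------------------------------

def _pooled_ions(maps: list[IonMap]) -> pd.DataFrame:
    frames = []
    for mp in sorted(maps, key=lambda m: m.map_id):
        df = mp.ions[list(IonMap.ION_COLUMNS)].copy()
        df["map_id"] = mp.map_id
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=list(IonMap.ION_COLUMNS) + ["map_id"])
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled.sort_values(
        ["z", "mz", "rt_min", "map_id", "ion_id"], kind="mergesort"
    ).reset_index(drop=True)
    return pooled


def _block_ids(pooled: pd.DataFrame, mz_tol_ppm: float) -> np.ndarray:
    """Coarse single-linkage blocks over sorted (z, mz)."""
    mz = pooled["mz"].to_numpy()
    z = pooled["z"].to_numpy()
    new_block = np.ones(len(pooled), dtype=bool)
    if len(pooled) > 1:
        gap_ppm = (mz[1:] - mz[:-1]) / mz[:-1] * 1e6
        new_block[1:] = (z[1:] != z[:-1]) | (gap_ppm > mz_tol_ppm)
    return np.cumsum(new_block)


def _confident_features(
    maps: list[IonMap], config: AlignmentConfig
) -> pd.DataFrame:
    """Features usable for RT refinement without an RT gate.

    Blocks (by charge and m/z only) in which no map contributes more than one
    ion, observed in at least ``min_maps_for_secondary`` maps, are taken as
    the same underlying feature regardless of current RT error.
    """
    pooled = _pooled_ions(maps)
    pooled["block"] = _block_ids(pooled, config.mz_tol_ppm)
    grp = pooled.groupby("block")
    n_maps = grp["map_id"].nunique()
    n_ions = grp.size()
    good = n_maps[(n_maps == n_ions) & (n_maps >= config.min_maps_for_secondary)].index
    return pooled[pooled["block"].isin(good)].copy()


def _fit_correction(
    rts: np.ndarray,
    residuals: np.ndarray,
    rt_range: tuple[float, float],
    n_knots: int,
) -> RtWarp:
    """Monotone piecewise-linear correction from binned median residuals."""
    knots = np.linspace(rt_range[0], rt_range[1], n_knots)
    centers, meds = [], []
    edges = np.concatenate([[-np.inf], (knots[:-1] + knots[1:]) / 2, [np.inf]])
    for k in range(n_knots):
        sel = (rts >= edges[k]) & (rts < edges[k + 1])
        if sel.sum() >= 3:
            centers.append(knots[k])
            meds.append(np.median(residuals[sel]))
    if len(centers) < 2:
        return identity_warp("")
    targets = knots + np.interp(knots, centers, meds)
    # enforce strict monotonicity of the corrected knots
    eps = 1e-9 * max(1.0, rt_range[1] - rt_range[0])
    for k in range(1, n_knots):
        if targets[k] <= targets[k - 1]:
            targets[k] = targets[k - 1] + eps
    return RtWarp(map_id="", kind="piecewise_linear", knots_obs=knots, knots_ref=targets)


def refine_rt_secondary(
    maps: list[IonMap], config: AlignmentConfig | None = None
) -> tuple[list[IonMap], dict[str, RtWarp]]:
    """Iterative piecewise-linear fine-tuning against the cross-map consensus.

    Returns the refined maps and the *total* correction applied per map
    (composition of the per-iteration corrections, sampled on a knot grid).
    The median absolute RT residual of the confident features is
    non-increasing across accepted iterations.
    """
    config = config or AlignmentConfig()
    if len(maps) < 2:
        return list(maps), {m.map_id: identity_warp(m.map_id) for m in maps}
    current = list(maps)
    total: dict[str, RtWarp] = {m.map_id: identity_warp(m.map_id) for m in maps}
    prev_err = np.inf
    for _ in range(config.max_refine_iter):
        feats = _confident_features(current, config)
        if feats.empty:
            warnings.warn("no common features for secondary RT refinement")
            break
        consensus = feats.groupby("block")["rt_min"].transform("median")
        feats = feats.assign(residual=consensus - feats["rt_min"])
        err = float(feats["residual"].abs().median())
        if err >= prev_err - config.refine_tol:
            break
        prev_err = err
        updated = []
        for mp in current:
            sub = feats[feats["map_id"] == mp.map_id]
            rt_all = mp.ions["rt_min"].to_numpy()
            if len(sub) < 6 or len(rt_all) == 0:
                updated.append(mp)
                continue
            rt_range = (float(rt_all.min()), float(rt_all.max()))
            corr = _fit_correction(
                sub["rt_min"].to_numpy(),
                sub["residual"].to_numpy(),
                rt_range,
                config.n_rt_knots,
            )
            if corr.kind == "affine":  # not enough bins: leave unchanged
                updated.append(mp)
                continue
            corr.map_id = mp.map_id
            updated.append(apply_warp(mp, corr))
            prev_total = total[mp.map_id]
            grid = np.linspace(rt_range[0] - 5, rt_range[1] + 5, 4 * config.n_rt_knots)
            total[mp.map_id] = RtWarp(
                map_id=mp.map_id,
                kind="piecewise_linear",
                knots_obs=grid,
                knots_ref=corr(prev_total(grid)) if prev_total.kind != "affine" else corr(grid),
            )
        current = updated
    return current, total


# ---------------------------------------------------------------------------
# Ion matching
# ---------------------------------------------------------------------------

def _match_block(block: pd.DataFrame, config: AlignmentConfig) -> list[list[int]]:
    """Greedy-by-map optimal assignment within one coarse block.

    Maps are visited in sorted order; each map's ions are assigned to
    existing groups by solving a rectangular linear assignment on the
    combined distance (ppm normalized by tolerance, plus a small RT
    tie-break term); infeasible pairs (beyond either tolerance) start new
    groups. With two maps this reduces to the exact minimum-total-distance
    one-to-one matching.
    """
    groups: list[dict] = []   # consensus state
    members: list[list[int]] = []
    for map_id, sub in block.groupby("map_id", sort=True):
        idx = sub.index.to_numpy()
        mzs = sub["mz"].to_numpy()
        rts = sub["rt_min"].to_numpy()
        if not groups:
            for j in range(len(idx)):
                groups.append({"mz": mzs[j], "rt": rts[j], "n": 1})
                members.append([idx[j]])
            continue
        g_mz = np.array([g["mz"] for g in groups])
        g_rt = np.array([g["rt"] for g in groups])
        ppm = np.abs(mzs[:, None] - g_mz[None, :]) / g_mz[None, :] * 1e6
        drt = np.abs(rts[:, None] - g_rt[None, :])
        cost = ppm / config.mz_tol_ppm + _RT_TIEBREAK * drt / config.rt_tol_min
        cost[(ppm > config.mz_tol_ppm) | (drt > config.rt_tol_min)] = _BIG
        rows, cols = linear_sum_assignment(cost)
        assigned = set()
        for r, c in zip(rows, cols):
            if cost[r, c] < _BIG / 2:
                g = groups[c]
                members[c].append(idx[r])
                g["mz"] = (g["mz"] * g["n"] + mzs[r]) / (g["n"] + 1)
                g["rt"] = (g["rt"] * g["n"] + rts[r]) / (g["n"] + 1)
                g["n"] += 1
                assigned.add(r)
        for r in range(len(idx)):
            if r not in assigned:
                groups.append({"mz": mzs[r], "rt": rts[r], "n": 1})
                members.append([idx[r]])
    return members


@dataclass
class MatchResult:
    """Long assignment table plus per-group consensus."""

    assignments: pd.DataFrame   # group_id + pooled ion columns
    groups: pd.DataFrame        # group_id, mz, rt, z, n_maps, peptide, protein


def match_ions(maps: list[IonMap], config: AlignmentConfig | None = None) -> MatchResult:
    """Group ions across maps on (m/z, RT, z); one ion per map per group."""
    config = config or AlignmentConfig()
    pooled = _pooled_ions(maps)
    if pooled.empty:
        empty = pooled.assign(group_id=pd.Series(dtype=int))
        return MatchResult(
            assignments=empty,
            groups=pd.DataFrame(
                columns=["group_id", "mz", "rt", "z", "n_maps", "peptide", "protein"]
            ),
        )
    pooled["block"] = _block_ids(pooled, config.mz_tol_ppm)
    group_of = np.full(len(pooled), -1, dtype=int)
    next_gid = 0
    for _, block in pooled.groupby("block", sort=True):
        if len(block) == 1:
            group_of[block.index[0]] = next_gid
            next_gid += 1
            continue
        for member_idx in _match_block(block, config):
            group_of[np.asarray(member_idx)] = next_gid
            next_gid += 1
    pooled["group_id"] = group_of

    def _first_label(s: pd.Series) -> str:
        vals = [v for v in s if isinstance(v, str) and v]
        return vals[0] if vals else ""

    groups = (
        pooled.groupby("group_id")
        .agg(
            mz=("mz", "mean"),
            rt=("rt_min", "mean"),
            z=("z", "first"),
            n_maps=("map_id", "nunique"),
            peptide=("peptide", _first_label),
            protein=("protein", _first_label),
            is_internal_standard=("is_internal_standard", "any"),
        )
        .reset_index()
    )
    return MatchResult(assignments=pooled, groups=groups)


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def _log2_matrix(result: MatchResult) -> pd.DataFrame:
    mat = result.assignments.pivot_table(
        index="group_id", columns="map_id", values="intensity", aggfunc="first"
    )
    return np.log2(mat)


def normalization_objective(matrix: pd.DataFrame, offsets: pd.Series) -> float:
    """Sum of squared deviations from the per-ion cross-map mean (observed cells)."""
    shifted = matrix.add(offsets, axis=1)
    dev = shifted.sub(shifted.mean(axis=1, skipna=True), axis=0)
    return float((dev**2).sum().sum())


@dataclass
class NormalizationResult:
    offsets: pd.Series              # log2 additive offset per map, sums to zero
    matrix: pd.DataFrame            # normalized log2 intensities, NaN = missing
    objective: float
    n_iter: int


def normalize_intensities(
    result: MatchResult,
    maps: list[IonMap] | None = None,
    config: AlignmentConfig | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> NormalizationResult:
    """Per-map additive log2 offsets by alternating closed-form updates.

    Default (L2) objective: sum over observed cells of the squared deviation
    of the shifted intensity from its per-ion cross-map mean. The L1 variant
    replaces means by medians. Offsets are centered to sum to zero.
    """
    config = config or AlignmentConfig()
    matrix = _log2_matrix(result)
    if matrix.shape[1] < 2:
        raise ValueError("normalization requires at least two maps")
    observed = matrix.notna()
    if not (observed.sum(axis=1) >= 2).any():
        raise ValueError("no ion observed in two or more maps")
    offsets = pd.Series(0.0, index=matrix.columns)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        shifted = matrix.add(offsets, axis=1)
        if config.normalization == "L2_log":
            row_center = shifted.mean(axis=1, skipna=True)
        else:
            row_center = shifted.median(axis=1, skipna=True)
        resid = -shifted.sub(row_center, axis=0)  # m_i - (x_ij + c_j)
        if config.normalization == "L2_log":
            delta = resid.mean(axis=0, skipna=True)
        else:
            delta = resid.median(axis=0, skipna=True)
        offsets = offsets + delta.fillna(0.0)
        if float(delta.abs().max()) < tol:
            break
    offsets = offsets - offsets.mean()
    normalized = matrix.add(offsets, axis=1)
    return NormalizationResult(
        offsets=offsets,
        matrix=normalized,
        objective=normalization_objective(matrix, offsets),
        n_iter=n_iter,
    )


@dataclass
class FeatureMatrix:
    """Feature-by-map table of normalized log2 intensities with metadata."""

    data: pd.DataFrame              # index group_id, columns map_ids
    meta: pd.DataFrame              # index group_id: mz, rt, z, peptide, protein, ...
    offsets: pd.Series              # per-map log2 normalization offsets

    @property
    def mask(self) -> pd.DataFrame:
        return self.data.isna()


def build_feature_matrix(
    result: MatchResult, norm: NormalizationResult
) -> FeatureMatrix:
    meta = result.groups.set_index("group_id")[
        ["mz", "rt", "z", "n_maps", "peptide", "protein", "is_internal_standard"]
    ]
    data = norm.matrix.reindex(meta.index)
    return FeatureMatrix(data=data, meta=meta, offsets=norm.offsets)
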