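"""Synthetic ground-truth generators for the indirect discovery pipeline.

Everything the pipeline consumes can be simulated here with known truth:

* random proteomes with in-silico tryptic digests and per-protein
  tumor/control fold changes ("spiked" differential proteins);
* paired tumor/control peptide-ion maps per discovery platform, with a
  monotone retention-time drift, per-map intensity scale offsets,
  multiplicative log-normal intensity noise and left-censoring at a
  detection floor;
* a fixed three-platform membership fixture whose Venn region counts are
  consistent with the published per-platform candidate totals;
* serum cohorts whose per-marker case/control log-normal marginals are
  calibrated to published median/IQR summary statistics;
* paired serum/plasma draws for concordance checks.

Peptide-level eligibility mirrors the enrichment chemistry the discovery
programs rely on: a tryptic peptide of 5-25 residues is observable iff it
carries a cysteine (ICAT capture) or an N-linked glycosylation sequon
N-X-S/T with X != P (hydrazide capture).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

__all__ = [
    "SyntheticProtein",
    "ProteomeConfig",
    "MapSimConfig",
    "CohortSimConfig",
    "IonMap",
    "INTERNAL_STANDARDS",
    "MARKER_CALIBRATION",
    "MARKER_NAMES",
    "tryptic_digest",
    "is_eligible_peptide",
    "generate_proteome",
    "reference_ion_table",
    "generate_ion_map_pair",
    "generate_platform_experiment",
    "generate_discovery_fixture",
    "fixture_annotations",
    "calibrate_lognormal",
    "default_marker_params",
    "generate_serum_cohort",
    "generate_paired_serum_plasma",
]

PLATFORMS = ("tissue", "cell_line", "conditioned_medium")
LOCALIZATIONS = ("secreted", "cell_membrane", "other")

# Retention-time anchor peptides spiked into every run (iRT-style standards).
INTERNAL_STANDARDS: dict[str, float] = {
    "SSAAPPPPPR": 8.0,
    "GISNEGQNASIK": 18.0,
    "HVLTSIGEK": 28.0,
    "DIPVPKPK": 38.0,
    "IGDYAGIK": 48.0,
    "TASEFDSAIAQDK": 58.0,
    "SAAGAFGPELSR": 68.0,
    "ELGQSGVDTYLQTK": 78.0,
    "GLILVGGYGTR": 88.0,
    "SFANQPLEVVYSK": 98.0,
    "LTILEELR": 104.0,
    "NGFILDGFPR": 112.0,
}

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# Approximate vertebrate residue frequencies (normalised below).
_AA_W = np.array(
    [7.0, 2.3, 4.7, 7.1, 3.7, 6.6, 2.6, 4.3, 5.7, 10.0,
     2.1, 3.6, 6.3, 4.8, 5.6, 8.3, 5.3, 6.0, 1.2, 2.7]
)
_AA_P = _AA_W / _AA_W.sum()

_SEQUON = re.compile(r"N[^P][ST]")


def tryptic_digest(sequence: str) -> list[str]:
    """Cleave after K or R, except when the next residue is P.

    No missed cleavages are produced.
    """
    peptides: list[str] = []
    start = 0
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == n or sequence[i + 1] != "P"):
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < n:
        peptides.append(sequence[start:])
    return peptides


def is_eligible_peptide(peptide: str) -> bool:
    """Observable by the enrichment chemistry: Cys or N-X-S/T sequon (X != P)."""
    return "C" in peptide or bool(_SEQUON.search(peptide))


@dataclass
class SyntheticProtein:
    """A simulated protein with its digest and ground-truth fold change."""

    accession: str
    localization: str
    peptides: list[str]          # tryptic peptides of length 5-25
    eligible: list[bool]         # Cys / sequon flag per peptide
    true_fold_change: float = 1.0

    def __post_init__(self) -> None:
        if self.localization not in LOCALIZATIONS:
            raise ValueError(f"unknown localization {self.localization!r}")
        if not self.true_fold_change > 0:
            raise ValueError("fold change must be positive")
        for pep in self.peptides:
            if not 5 <= len(pep) <= 25:
                raise ValueError(f"peptide length outside [5, 25]: {pep!r}")

    @property
    def eligible_peptides(self) -> list[str]:
        return [p for p, e in zip(self.peptides, self.eligible) if e]


@dataclass
class ProteomeConfig:
    mean_length: int = 350
    differential_fold: float = 8.0
    p_secreted: float = 0.25
    p_membrane: float = 0.25
    seed: int = 0


def generate_proteome(
    n_proteins: int, frac_differential: float, config: ProteomeConfig | None = None
) -> list[SyntheticProtein]:
    """Simulate ``n_proteins`` random proteins, spiking a fraction as differential.

    Spiked proteins carry ``config.differential_fold`` as the tumor/control
    fold change; all others are null (fold 1.0). Localization is drawn
    independently of spike status.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not 0.0 <= frac_differential <= 1.0:
        raise ValueError("frac_differential must lie in [0, 1]")
    config = config or ProteomeConfig()
    rng = np.random.default_rng(config.seed)
    n_spiked = int(round(frac_differential * n_proteins))
    spiked = set(rng.choice(n_proteins, size=n_spiked, replace=False).tolist())
    p_other = 1.0 - config.p_secreted - config.p_membrane
    proteome = []
    for i in range(n_proteins):
        length = max(40, int(rng.normal(config.mean_length, config.mean_length / 4)))
        seq = "".join(rng.choice(_AA, size=length, p=_AA_P))
        peps = [p for p in tryptic_digest(seq) if 5 <= len(p) <= 25]
        loc = rng.choice(
            LOCALIZATIONS, p=[config.p_secreted, config.p_membrane, p_other]
        )
        proteome.append(
            SyntheticProtein(
                accession=f"SP{i:05d}",
                localization=str(loc),
                peptides=peps,
                eligible=[is_eligible_peptide(p) for p in peps],
                true_fold_change=config.differential_fold if i in spiked else 1.0,
            )
        )
    return proteome


@lru_cache(maxsize=200_000)
def _mz(peptide: str, z: int) -> float:
    return float(_ptmass.fast_mass(peptide, charge=z))


@dataclass
class MapSimConfig:
    """Noise model for one platform's paired tumor/control ion maps.

    Retention-time drift is a random monotone quadratic warp per map;
    intensities get a per-map log2 offset, multiplicative log-normal noise,
    optional uniform dropout, and left-censoring below ``detection_floor``.
    """

    n_pairs_per_platform: int = 4
    platform: str = "tissue"
    rt_drift: tuple[float, float, float] | None = None  # fixed (a, b, c) for all maps
    intensity_log_offset: float | None = None           # fixed log2 offset for all maps
    drift_offset_range: tuple[float, float] = (-2.0, 2.0)
    drift_slope_range: tuple[float, float] = (0.95, 1.05)
    drift_quad_range: tuple[float, float] = (-2e-4, 2e-4)
    offset_range: tuple[float, float] = (-1.0, 1.0)
    noise_sd: float = 0.25           # log2 scale
    dropout_rate: float = 0.0
    detection_floor: float = 2.0 ** 16
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    rt_range: tuple[float, float] = (5.0, 115.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.detection_floor <= 0:
            raise ValueError("detection_floor must be positive")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.rt_drift is not None:
            _check_monotone_warp(self.rt_drift, self.rt_range)


def _check_monotone_warp(coef: Sequence[float], rt_range: tuple[float, float]) -> None:
    _, b, c = coef
    lo, hi = 0.0, rt_range[1] + 10.0
    if b + 2 * c * lo <= 0 or b + 2 * c * hi <= 0:
        raise ValueError("rt drift warp is not strictly increasing on the RT range")


@dataclass
class IonMap:
    """One sample's peptide-ion peak list plus experiment metadata."""

    map_id: str
    sample_id: str
    condition: str                      # tumor | control
    platform: str
    ions: pd.DataFrame                  # ion_id, mz, rt_min, z, intensity, peptide,
    paired_map_id: str | None = None    # protein, is_internal_standard

    ION_COLUMNS = (
        "ion_id", "mz", "rt_min", "z", "intensity",
        "peptide", "protein", "is_internal_standard",
    )


def reference_ion_table(
    proteome: Sequence[SyntheticProtein], config: MapSimConfig
) -> pd.DataFrame:
    """Deterministic theoretical ion table shared by every map of an experiment.

    One row per (eligible peptide, charge in {2, 3}): theoretical m/z, a
    reference RT drawn once per peptide, and a base log2 intensity drawn once
    per ion. Internal standards are appended with their known anchor RTs.
    """
    rng = np.random.default_rng([config.seed, 7_919])
    rows = []
    lo, hi = config.rt_range
    for prot in proteome:
        for pep, ok in zip(prot.peptides, prot.eligible):
            if not ok:
                continue
            ref_rt = rng.uniform(lo, hi)
            for z in (2, 3):
                rows.append(
                    (
                        pep,
                        prot.accession,
                        z,
                        _mz(pep, z),
                        ref_rt,
                        rng.normal(config.base_log2_mean, config.base_log2_sd),
                        prot.true_fold_change,
                        False,
                    )
                )
    for pep, ref_rt in INTERNAL_STANDARDS.items():
        rows.append((pep, "STANDARD", 2, _mz(pep, 2), ref_rt, 20.0, 1.0, True))
    table = pd.DataFrame(
        rows,
        columns=[
            "peptide", "protein", "z", "mz", "ref_rt",
            "base_log2", "fold", "is_internal_standard",
        ],
    )
    table.insert(0, "ion_id", [f"ref{i:06d}" for i in range(len(table))])
    return table


def _simulate_map(
    ref: pd.DataFrame,
    config: MapSimConfig,
    rng: np.random.Generator,
    map_id: str,
    sample_id: str,
    condition: str,
    paired_map_id: str | None,
) -> IonMap:
    if config.rt_drift is not None:
        a, b, c = config.rt_drift
    else:
        for _ in range(100):
            a = rng.uniform(*config.drift_offset_range)
            b = rng.uniform(*config.drift_slope_range)
            c = rng.uniform(*config.drift_quad_range)
            try:
                _check_monotone_warp((a, b, c), config.rt_range)
                break
            except ValueError:
                continue
    offset = (
        config.intensity_log_offset
        if config.intensity_log_offset is not None
        else rng.uniform(*config.offset_range)
    )
    rt = a + b * ref["ref_rt"].to_numpy() + c * ref["ref_rt"].to_numpy() ** 2
    log2_fold = np.where(condition == "tumor", np.log2(ref["fold"].to_numpy()), 0.0)
    noise = rng.normal(0.0, config.noise_sd, size=len(ref))
    std = ref["is_internal_standard"].to_numpy()
    log2_int = ref["base_log2"].to_numpy() + offset + log2_fold + noise
    # standards are anchors: scale offset applies, biological fold/noise do not
    log2_int[std] = ref["base_log2"].to_numpy()[std] + offset
    intensity = 2.0 ** log2_int
    keep = std | (intensity >= config.detection_floor)
    if config.dropout_rate > 0:
        keep &= std | (rng.uniform(size=len(ref)) >= config.dropout_rate)
    ions = pd.DataFrame(
        {
            "ion_id": [f"{map_id}:{i}" for i in ref.index[keep]],
            "mz": ref["mz"].to_numpy()[keep],
            "rt_min": rt[keep],
            "z": ref["z"].to_numpy()[keep],
            "intensity": intensity[keep],
            "peptide": ref["peptide"].to_numpy()[keep],
            "protein": ref["protein"].to_numpy()[keep],
            "is_internal_standard": std[keep],
        }
    )
    return IonMap(
        map_id=map_id,
        sample_id=sample_id,
        condition=condition,
        platform=config.platform,
        paired_map_id=paired_map_id,
        ions=ions.reset_index(drop=True),
    )


def generate_ion_map_pair(
    proteome: Sequence[SyntheticProtein],
    config: MapSimConfig,
    pair_index: int,
) -> tuple[IonMap, IonMap]:
    """Simulate one paired (tumor, control) ion-map draw.

    Tumor intensities of spiked proteins are multiplied by their ground-truth
    fold change; everything else (drift, scale offset, noise, censoring,
    dropout) is condition-independent in distribution.
    """
    if len(proteome) == 0:
        raise ValueError("proteome must be non-empty")
    ref = reference_ion_table(proteome, config)
    tag = f"{config.platform}_p{pair_index:02d}"
    t_id, c_id = f"{tag}_tumor", f"{tag}_control"
    rng_t = np.random.default_rng([config.seed, pair_index, 0])
    rng_c = np.random.default_rng([config.seed, pair_index, 1])
    tumor = _simulate_map(ref, config, rng_t, t_id, f"{tag}_T", "tumor", c_id)
    control = _simulate_map(ref, config, rng_c, c_id, f"{tag}_N", "control", t_id)
    return tumor, control


def generate_platform_experiment(
    proteome: Sequence[SyntheticProtein], config: MapSimConfig
) -> list[IonMap]:
    """All paired maps for one platform (2 * n_pairs_per_platform maps)."""
    maps: list[IonMap] = []
    for k in range(config.n_pairs_per_platform):
        tumor, control = generate_ion_map_pair(proteome, config, k)
        maps.extend([tumor, control])
    return maps


# ---------------------------------------------------------------------------
# Three-platform discovery fixture (Venn-consistent membership table)
# ---------------------------------------------------------------------------

#: Region sizes of the packaged 179-marker membership fixture. Per-platform
#: totals reconstruct to tissue 113, cell line 86, conditioned medium 65;
#: the tissue pairwise split (30, 12) is a fixed documented choice among the
#: solutions of the inclusion-exclusion system.
FIXTURE_REGIONS: dict[tuple[str, ...], int] = {
    ("tissue",): 57,
    ("cell_line",): 27,
    ("conditioned_medium",): 24,
    ("tissue", "cell_line"): 30,
    ("tissue", "conditioned_medium"): 12,
    ("cell_line", "conditioned_medium"): 15,
    ("tissue", "cell_line", "conditioned_medium"): 14,
}

#: Of the 29 markers shared by conditioned medium and cell-line membranes,
#: 9 were resolved in the same cell line; carried as fixture metadata.
FIXTURE_N_SAME_CELL_LINE = 9


def generate_discovery_fixture() -> pd.DataFrame:
    """Fixed 179-marker platform-membership table.

    Columns: accession, one boolean per platform, and ``same_cell_line``
    (True for 9 of the 29 markers found in both conditioned medium and
    cell-line membrane preparations).
    """
    rows = []
    i = 0
    for region, count in FIXTURE_REGIONS.items():
        for _ in range(count):
            i += 1
            rows.append(
                {
                    "accession": f"M{i:03d}",
                    **{p: p in region for p in PLATFORMS},
                }
            )
    df = pd.DataFrame(rows)
    cm_cl = df["cell_line"] & df["conditioned_medium"]
    flag = np.zeros(len(df), dtype=bool)
    flag[np.flatnonzero(cm_cl.to_numpy())[:FIXTURE_N_SAME_CELL_LINE]] = True
    df["same_cell_line"] = flag
    return df


#: Protein-class counts over the 141 annotated fixture markers; chosen so the
#: round-half-up percentages of the classified subset are 14/14/13/10/9/8/8
#: and annotation coverage is 141/179 = 79 %.
FIXTURE_CLASS_COUNTS: dict[str, int] = {
    "receptor": 20,
    "cell adhesion molecule": 20,
    "hydrolase": 18,
    "defense/immunity protein": 14,
    "protease": 13,
    "enzyme modulator": 11,
    "signaling molecule": 11,
    "other": 34,
}


def fixture_annotations() -> pd.DataFrame:
    """Static annotation table (synthetic stand-in for a curated class/localization snapshot).

    141 of the 179 fixture markers carry a protein class; the rest are
    unclassified (empty string). Localization alternates between the two
    compartments every fixture candidate is constrained to.
    """
    fixture = generate_discovery_fixture()
    classes: list[str] = []
    for cls, count in FIXTURE_CLASS_COUNTS.items():
        classes.extend([cls] * count)
    classes.extend([""] * (len(fixture) - len(classes)))
    # deterministic interleave so every Venn region mixes classes
    rng = np.random.default_rng(20150716)
    order = rng.permutation(len(fixture))
    assigned = np.empty(len(fixture), dtype=object)
    assigned[order] = classes
    return pd.DataFrame(
        {
            "accession": fixture["accession"],
            "protein_class": assigned,
            "localization": np.where(
                np.arange(len(fixture)) % 2 == 0, "secreted", "cell_membrane"
            ),
            "pathway": "",
        }
    )


# ---------------------------------------------------------------------------
# Serum cohorts
# ---------------------------------------------------------------------------

#: Published serum summary statistics used as generator calibration targets:
#: marker -> group -> (median, Q1, Q3) in ng/mL.
MARKER_CALIBRATION: dict[str, dict[str, tuple[float, float, float]]] = {
    "CEA": {"control": (1.65, 0.85, 2.92), "case": (2.68, 1.85, 4.90)},
    "MDK": {"control": (0.15, 0.04, 0.35), "case": (0.43, 0.20, 0.66)},
    "MMP2": {"control": (207.0, 184.0, 234.0), "case": (207.0, 171.0, 254.0)},
    "SLPI": {"control": (39.6, 34.8, 46.2), "case": (43.3, 35.5, 54.5)},
    "TFPI": {"control": (39.7, 25.6, 55.1), "case": (54.1, 29.1, 70.3)},
    "TIMP1": {"control": (302.0, 269.0, 346.0), "case": (361.0, 306.0, 440.0)},
    "CYFRA 21-1": {"control": (0.58, 0.00, 1.05), "case": (1.60, 0.91, 3.00)},
    "OPN": {"control": (19.3, 10.0, 31.0), "case": (31.4, 16.7, 52.4)},
    "SCC": {"control": (0.58, 0.34, 0.93), "case": (1.21, 0.55, 1.70)},
}

MARKER_NAMES = tuple(MARKER_CALIBRATION)

_Z75 = 0.6744897501960817  # standard normal upper quartile


def calibrate_lognormal(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (location, scale) on the natural-log scale from median/IQR.

    location = ln(median); scale = (ln Q3 - ln Q1) / (2 * z_0.75). When the
    printed lower quartile is 0 (possible for assays with values below the
    limit of detection) the scale is taken from the upper half-spread only:
    (ln Q3 - ln median) / z_0.75.
    """
    if median <= 0 or q3 <= 0:
        raise ValueError("median and Q3 must be positive")
    if q3 < median or (q1 > 0 and q1 > median):
        raise ValueError("quartiles must bracket the median")
    if q1 > 0:
        sigma = (np.log(q3) - np.log(q1)) / (2 * _Z75)
    else:
        sigma = (np.log(q3) - np.log(median)) / _Z75
    return float(np.log(median)), float(sigma)


def default_marker_params(
    null_markers: Sequence[str] = (),
) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-marker log-normal parameters calibrated to the published table.

    ``null_markers`` lists markers whose case group is forced to the control
    calibration (pure-noise markers with no case/control signal).
    """
    params: dict[str, dict[str, tuple[float, float]]] = {}
    for marker, groups in MARKER_CALIBRATION.items():
        ctrl = calibrate_lognormal(*groups["control"])
        case = ctrl if marker in null_markers else calibrate_lognormal(*groups["case"])
        params[marker] = {"control": ctrl, "case": case}
    return params


@dataclass
class CohortSimConfig:
    """Serum-cohort generator settings.

    Marker concentrations are correlated log-normals on the natural-log
    scale; cases share a latent severity variable that also drives lesion
    size, so a good panel score correlates with nodule size by construction.
    """

    marker_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=default_marker_params
    )
    n_cases: int = 94
    n_controls: int = 189
    correlation: np.ndarray | None = None   # marker-marker, log scale
    severity_coupling: float = 0.5          # rho linking case markers to latent severity
    case_size_log_median: float = np.log(2.6)
    case_size_log_sd: float = 0.6
    case_size_range: tuple[float, float] = (0.8, 12.0)
    control_nodule_fraction: float = 0.44
    control_size_log_median: float = np.log(0.5)
    control_size_log_sd: float = 0.45
    control_size_range: tuple[float, float] = (0.2, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        for marker, groups in self.marker_params.items():
            for grp, (_, sigma) in groups.items():
                if sigma < 0:
                    raise ValueError(f"negative scale for {marker}/{grp}")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            m = len(self.marker_params)
            if R.shape != (m, m) or not np.allclose(R, R.T):
                raise ValueError("correlation must be a symmetric m x m matrix")
            if not np.allclose(np.diag(R), 1.0):
                raise ValueError("correlation diagonal must be 1")
            if np.linalg.eigvalsh(R).min() < -1e-10:
                raise ValueError("correlation matrix is not positive semi-definite")


_HISTOLOGY = np.array(
    ["adenocarcinoma", "BAC", "large_cell", "NSCLC_NOS", "neuroendocrine", "squamous_cell"]
)
_HISTOLOGY_P = np.array([63, 4, 6, 4, 2, 15], dtype=float) / 94.0


def _correlated_normals(
    rng: np.random.Generator, n: int, m: int, R: np.ndarray | None
) -> np.ndarray:
    z = rng.standard_normal((n, m))
    if R is None:
        return z
    w, V = np.linalg.eigh(np.asarray(R, dtype=float))
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return z @ L.T


def generate_serum_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """One subject per row: id, label, covariates, then ng/mL per marker."""
    rng = np.random.default_rng(config.seed)
    markers = list(config.marker_params)
    m = len(markers)
    frames = []
    for label, n in (("control", config.n_controls), ("case", config.n_cases)):
        z = _correlated_normals(rng, n, m, config.correlation)
        if label == "case":
            u = rng.standard_normal(n)
            rho = config.severity_coupling
            z = np.sqrt(max(0.0, 1 - rho**2)) * z + rho * u[:, None]
            size = np.exp(config.case_size_log_median + config.case_size_log_sd * u)
            size = np.clip(size, *config.case_size_range)
            age = rng.normal(66.6, 9.6, n)
            pack = np.clip(rng.normal(43.9, 20.6, n), 0, None)
            sex = np.where(rng.uniform(size=n) < 33 / 94, "M", "F")
            stage = np.repeat("I", n)
            hist = rng.choice(_HISTOLOGY, size=n, p=_HISTOLOGY_P)
        else:
            has_nodule = rng.uniform(size=n) < config.control_nodule_fraction
            size = np.exp(
                rng.normal(config.control_size_log_median, config.control_size_log_sd, n)
            )
            size = np.where(has_nodule, np.clip(size, *config.control_size_range), np.nan)
            age = rng.normal(62.1, 11.8, n)
            pack = np.clip(rng.normal(37.6, 21.7, n), 0, None)
            sex = np.where(rng.uniform(size=n) < 109 / 189, "M", "F")
            stage = np.repeat("", n)
            hist = np.repeat("", n)
        df = pd.DataFrame(
            {
                "subject_id": [f"{label[:4]}{i:04d}" for i in range(n)],
                "label": label,
                "age": np.round(age, 1),
                "sex": sex,
                "pack_years": np.round(pack, 1),
                "nodule_size_cm": np.round(size, 2),
                "stage": stage,
                "histology": hist,
            }
        )
        for j, marker in enumerate(markers):
            mu, sigma = config.marker_params[marker][label]
            df[marker] = np.exp(mu + sigma * z[:, j])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_paired_serum_plasma(
    n_subjects: int,
    concordance_sd: float = 0.1,
    seed: int = 0,
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Paired serum/plasma draws per marker with a controllable matrix effect.

    Plasma = serum x exp(N(0, concordance_sd)) on the log scale; sd 0 gives
    perfect per-marker concordance.
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    rng = np.random.default_rng(seed)
    params = default_marker_params()
    markers = list(markers) if markers is not None else list(params)
    rows = []
    for marker in markers:
        mu, sigma = params[marker]["control"]
        serum = np.exp(mu + sigma * rng.standard_normal(n_subjects))
        plasma = serum * np.exp(rng.normal(0.0, concordance_sd, n_subjects))
        for i in range(n_subjects):
            rows.append((f"S{i:03d}", marker, serum[i], plasma[i]))
    return pd.DataFrame(rows, columns=["subject_id", "marker", "serum", "plasma"])
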