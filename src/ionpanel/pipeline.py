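"""End-to-end orchestration: simulate -> align -> discover -> integrate ->
verify -> train -> evaluate, with every artifact written to disk under a
provenance header (version, config hash, seed)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align as _align
from . import discover as _discover
from . import integrate as _integrate
from . import io as _io
from . import panel as _panel
from . import synth as _synth

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "align_experiment"]


@dataclass
class PipelineConfig:
    """Nested stage configs plus global seed; the demo defaults are small."""

    seed: int = 0
    n_proteins: int = 150
    frac_differential: float = 0.1
    n_pairs_per_platform: int = 3
    noise_sd: float = 0.25
    dropout_rate: float = 0.0
    alignment: _align.AlignmentConfig = field(default_factory=_align.AlignmentConfig)
    discovery: _discover.DiscoveryConfig = field(default_factory=_discover.DiscoveryConfig)
    n_cases: int = 94
    n_controls: int = 189
    alpha: float = 0.5
    n_bootstrap: int = 200
    lambda_grid: list[float] = field(
        default_factory=lambda: _panel.DEFAULT_LAMBDA_GRID.tolist()
    )
    null_markers: tuple[str, ...] = ("SLPI",)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def align_experiment(
    maps: list[_synth.IonMap], config: _align.AlignmentConfig
) -> _align.FeatureMatrix:
    """Primary + secondary RT normalization, matching, intensity normalization."""
    warped = [_align.apply_warp(m, _align.fit_primary_rt_warp(m)) for m in maps]
    refined, _ = _align.refine_rt_secondary(warped, config)
    matched = _align.match_ions(refined, config)
    norm = _align.normalize_intensities(matched, refined, config)
    return _align.build_feature_matrix(matched, norm)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, writing the artifact bundle; returns artifact paths.

    A failing stage aborts with :class:`StageError` naming the stage. Reruns
    with the same config and seed are bit-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    seed = config.seed

    def _stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise StageError(name, exc) from exc
        return deco

    @_stage("simulate")
    def sim():
        proteome = _synth.generate_proteome(
            config.n_proteins,
            config.frac_differential,
            _synth.ProteomeConfig(seed=seed),
        )
        per_platform_maps = {}
        for k, platform in enumerate(_synth.PLATFORMS):
            mc = _synth.MapSimConfig(
                n_pairs_per_platform=config.n_pairs_per_platform,
                platform=platform,
                noise_sd=config.noise_sd,
                dropout_rate=config.dropout_rate,
                seed=seed * 7 + k,
            )
            maps = _synth.generate_platform_experiment(proteome, mc)
            path = outdir / f"maps_{platform}.tsv"
            _io.write_ion_maps(maps, path, seed=seed, config=config)
            per_platform_maps[platform] = maps
            artifacts[f"maps_{platform}"] = str(path)
        cohort = _synth.generate_serum_cohort(
            _synth.CohortSimConfig(
                marker_params=_synth.default_marker_params(config.null_markers),
                n_cases=config.n_cases,
                n_controls=config.n_controls,
                seed=seed,
            )
        )
        cohort_path = outdir / "cohort.csv"
        _io.write_table(cohort, cohort_path, sep=",", seed=seed, config=config)
        artifacts["cohort"] = str(cohort_path)
        paired = _synth.generate_paired_serum_plasma(10, 0.1, seed=seed)
        _io.write_table(paired, outdir / "serum_plasma.csv", sep=",", seed=seed)
        artifacts["serum_plasma"] = str(outdir / "serum_plasma.csv")
        truth = {
            p.accession: {"fold": p.true_fold_change, "localization": p.localization}
            for p in proteome
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        artifacts["ground_truth"] = str(outdir / "ground_truth.json")
        annotations = pd.DataFrame(
            {
                "accession": [p.accession for p in proteome],
                "protein_class": "",
                "localization": [p.localization for p in proteome],
            }
        )
        return proteome, per_platform_maps, cohort, paired, annotations

    proteome, per_platform_maps, cohort, paired, annotations = sim

    @_stage("align")
    def aligned():
        out = {}
        for platform, maps in per_platform_maps.items():
            fm = align_experiment(maps, config.alignment)
            path = outdir / f"features_{platform}.tsv"
            _io.write_feature_matrix(fm, path, seed=seed, config=config)
            artifacts[f"features_{platform}"] = str(path)
            out[platform] = (fm, maps)
        return out

    @_stage("discover")
    def candidates():
        out = {}
        for platform, (fm, maps) in aligned.items():
            pairs = _discover.infer_pairs(maps)
            ratios = _discover.compute_peptide_ratios(
                fm, pairs, config.discovery.detection_floor
            )
            flagged = _discover.flag_differential_peptides(ratios, config.discovery)
            cand = _discover.aggregate_to_protein(flagged, annotations)
            retained, audit = _discover.apply_prioritization_filters(
                cand, config.discovery
            )
            path = outdir / f"candidates_{platform}.tsv"
            _io.write_table(audit, path, seed=seed, config=config)
            artifacts[f"candidates_{platform}"] = str(path)
            out[platform] = retained
        return out

    @_stage("integrate")
    def venn():
        membership = _integrate.integrate_platforms(candidates)
        part = _integrate.venn_partition(membership)
        path = outdir / "venn.json"
        path.write_text(
            json.dumps(
                {
                    "regions": {"+".join(k): v for k, v in part.region_counts.items()},
                    "total": part.total,
                    "per_platform_totals": part.per_platform_totals,
                    "exactly_one_pct": part.exactly_one_pct,
                    "all_three_pct": part.all_three_pct,
                },
                indent=2,
            )
        )
        artifacts["venn"] = str(path)
        _io.write_table(membership, outdir / "membership.tsv", seed=seed, config=config)
        artifacts["membership"] = str(outdir / "membership.tsv")
        return part

    @_stage("verify")
    def marker_table():
        rows = []
        for marker in _synth.MARKER_NAMES:
            s = _panel.summarize_marker(
                cohort.loc[cohort["label"] == "case", marker].to_numpy(),
                cohort.loc[cohort["label"] == "control", marker].to_numpy(),
                marker,
            )
            rows.append(
                {
                    "marker": marker,
                    "median_control": s.median_control,
                    "q1_control": s.iqr_control[0],
                    "q3_control": s.iqr_control[1],
                    "median_case": s.median_case,
                    "q1_case": s.iqr_case[0],
                    "q3_case": s.iqr_case[1],
                    "ks_D": s.ks_statistic,
                    "ks_p": s.ks_pvalue,
                    "auc": s.auc,
                }
            )
        table = pd.DataFrame(rows)
        _io.write_table(table, outdir / "marker_summary.csv", sep=",", seed=seed)
        artifacts["marker_summary"] = str(outdir / "marker_summary.csv")
        return table

    _ = marker_table

    @_stage("train")
    def model():
        X = cohort[list(_synth.MARKER_NAMES)].to_numpy(dtype=float)
        y = (cohort["label"] == "case").to_numpy().astype(int)
        selection = _panel.select_penalty_bootstrap(
            X, y,
            lambda_grid=np.asarray(config.lambda_grid),
            alpha=config.alpha,
            n_bootstrap=config.n_bootstrap,
            seed=seed,
        )
        pm = _panel.finalize_panel(
            X, y, selection, config.alpha, list(_synth.MARKER_NAMES)
        )
        (outdir / "panel_model.json").write_text(pm.to_json())
        artifacts["panel_model"] = str(outdir / "panel_model.json")
        return pm

    @_stage("evaluate")
    def report():
        controls = cohort["label"] == "control"
        has_nodule = cohort["nodule_size_cm"].notna()
        rep = _panel.evaluate_panel(
            model,
            cohort,
            subgroups={
                "nodule_controls": (controls & has_nodule).to_numpy(),
                "no_nodule_controls": (controls & ~has_nodule).to_numpy(),
            },
        )
        scores = model.score(cohort)
        case_rows = (cohort["label"] == "case").to_numpy()
        r, p = _panel.correlate_score_covariate(
            scores[case_rows], cohort.loc[case_rows, "nodule_size_cm"].to_numpy()
        )
        rep["nodule_size_correlation"] = {"r": r, "p": p}
        rep["serum_plasma_concordance"] = _panel.serum_plasma_concordance(
            paired
        ).to_dict()
        (outdir / "evaluation.json").write_text(json.dumps(rep, indent=2))
        artifacts["evaluation"] = str(outdir / "evaluation.json")
        return rep

    _ = venn, report
    (outdir / "artifacts.json").write_text(json.dumps(artifacts, indent=2))
    return artifacts
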