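"""End-to-end orchestration of the evaluation scheme.

``run_all`` chains: per-platform preprocessing → feature-wise merge →
exogenous-compound removal → biomarker selection + phenotype filter →
PCA trajectory → principal-curve MDS with per-animal AUC → RAUC with
re-regulation calls.  Every intermediate table is written as CSV; a
manifest records the config hash, seed and per-stage shapes so a rerun
with the same config and seed reproduces the outputs exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocessing as prep
from .config import PipelineConfig
from .containers import PeakTable, reports_frame
from .deregulation import compute_mds, compute_trajectory, fit_principal_curve, mds_auc
from .multivariate import fit_pca, pca_q2
from .rauc import common_reregulated, compute_rauc, relative_curves
from .screening import (
    detect_exogenous,
    remove_features,
    select_biomarkers,
    spearman_filter,
    union_biomarkers,
)
from .synthetic import generate_study, read_study, write_study

log = logging.getLogger("metaboeval")


def preprocess_platform(table: PeakTable, config: PipelineConfig):
    """Run the filter chain + normalization on one platform's features."""
    reports = []
    t, r = prep.filter_background(table, config.background_min_ratio)
    reports.append(r)
    # blanks have served their purpose; drop them before normalization
    t = t.subset_samples(t.sample_meta.index[t.sample_meta["sample_type"] != "blank"])
    t, r = prep.apply_80_rule(t, config.rule80_fraction)
    reports.append(r)
    t, r = prep.qc_rsd_filter(t, config.qc_max_rsd)
    reports.append(r)
    t = prep.normalize_total_intensity(t)
    if config.fusion_enabled:
        grouping = None
        if "fusion_window" in t.feature_meta.columns:
            grouping = t.feature_meta["fusion_window"]
        t, r = prep.fuse_ions(t, grouping, config.fusion_min_correlation)
        reports.append(r)
    return t, reports


def merge_platforms(tables: dict) -> PeakTable:
    """Feature-wise concatenation of per-platform tables.

    A sample row survives iff present on *all* platforms; mismatches raise
    with the offending ids rather than being dropped silently.
    """
    if not tables:
        raise ValueError("no platform tables to merge")
    items = list(tables.items())
    common = items[0][1].intensities.index
    for name, t in items[1:]:
        if not t.intensities.index.equals(common):
            a = set(common)
            b = set(t.intensities.index)
            raise ValueError(
                f"platform {name!r} sample mismatch: only-in-first={sorted(a - b)[:5]}, "
                f"only-in-{name}={sorted(b - a)[:5]}"
            )
    intensities = pd.concat([t.intensities for _, t in items], axis=1)
    feature_meta = pd.concat([t.feature_meta for _, t in items], axis=0)
    if intensities.columns.has_duplicates:
        raise ValueError("duplicate feature ids across platforms")
    return PeakTable(intensities, items[0][1].sample_meta.copy(), feature_meta)


def stage_preprocess(table: PeakTable, config: PipelineConfig):
    """Split by platform, preprocess each, merge back."""
    platforms = sorted(table.feature_meta["platform"].unique())
    per_platform = {}
    reports = []
    for pf in platforms:
        ids = table.feature_meta.index[table.feature_meta["platform"] == pf]
        sub = table.subset_features(ids)
        t, rs = preprocess_platform(sub, config)
        per_platform[pf] = t
        for r in rs:
            r.stage = f"{pf}:{r.stage}"
        reports.extend(rs)
    merged = merge_platforms(per_platform)
    return merged, reports


def stage_screen(table: PeakTable, phenotypes, config: PipelineConfig):
    """Exogenous removal, per-day biomarker selection, phenotype filter."""
    meta = table.sample_meta
    groups = sorted(meta.loc[table.study_ids, "group"].unique())
    treated = [g for g in groups if g not in (config.control_group, config.toxin_group)]
    exogenous = {}
    for g in treated:
        exogenous[g] = detect_exogenous(
            table,
            g,
            control_group=config.control_group,
            toxin_group=config.toxin_group,
            absence_fraction=config.absence_fraction,
        )
    all_exo = sorted({f for ids in exogenous.values() for f in ids})
    endo = remove_features(table, all_exo)

    records = []
    days = endo.days
    others = [g for g in groups if g != config.toxin_group]
    for day in days:
        for g in others:
            records.append(
                select_biomarkers(
                    endo,
                    config.toxin_group,
                    g,
                    day,
                    vip_threshold=config.vip_threshold,
                    p_threshold=config.p_threshold,
                    use_adjusted_p=config.use_adjusted_p,
                    cv_seed=config.seed,
                )
            )
    markers = union_biomarkers(records)
    markers = spearman_filter(markers, endo, phenotypes, cutoff=config.spearman_cutoff)
    return endo, exogenous, markers


def stage_trajectory(table: PeakTable, config: PipelineConfig):
    """PCA of the full preprocessed matrix + group-day trajectory."""
    filled = prep.impute_half_minimum(table)
    study = filled.study_matrix()
    scaled, _, _ = prep.pareto_scale(study)
    n_comp = min(10, scaled.shape[0] - 1, scaled.shape[1])
    pca = fit_pca(scaled, n_components=n_comp)
    pca.q2 = pca_q2(scaled, min(2, n_comp), seed=config.seed)
    traj = compute_trajectory(pca, table.sample_meta)
    return pca, traj


def stage_mds(table: PeakTable, marker_ids, config: PipelineConfig):
    """Principal-curve MDS on the filtered biomarker matrix."""
    if len(marker_ids) < 2:
        raise ValueError("too few biomarkers for MDS")
    sub = table.subset_features(marker_ids)
    filled = prep.impute_half_minimum(sub)
    study = filled.study_matrix()
    scaled, _, _ = prep.pareto_scale(study)
    meta = table.sample_meta
    baseline = meta.loc[table.study_ids, "day"].min()
    healthy = meta.index[
        (meta["sample_type"] == "study") & (meta["group"] == config.control_group)
    ]
    fit_matrix = scaled.loc[healthy] if config.fit_on_healthy_only else scaled
    curve = fit_principal_curve(
        fit_matrix,
        healthy_ids=healthy,
        variance_target=config.pc_variance_target,
        span=config.curve_span,
        tol=config.curve_tol,
        max_iter=config.curve_max_iter,
    )
    mds = compute_mds(curve, scaled, sample_meta=meta)
    auc_df, tests = mds_auc(mds)
    return curve, mds, auc_df, tests


def stage_rauc(table: PeakTable, marker_ids, config: PipelineConfig):
    curves = relative_curves(
        table,
        config.control_group,
        marker_ids,
        window_days=config.rauc_window,
        scale=config.rauc_scale,
    )
    result = compute_rauc(curves, toxin_group=config.toxin_group, alpha=config.rauc_alpha)
    groups = sorted(set(result.per_animal["group"]) - {config.toxin_group, config.control_group})
    sets = {"all_treated": groups} if len(groups) >= 2 else {}
    common = common_reregulated(result, sets) if sets else {}
    return curves, result, common


def run_all(config: PipelineConfig, table=None, phenotypes=None, truth=None) -> dict:
    """Execute the whole scheme; write every intermediate to ``config.outdir``.

    With no input table the synthetic study is generated from
    ``config.seed``.  Returns a dict of in-memory results.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.content_hash(), "seed": config.seed, "stages": {}}

    def note(stage, tab):
        manifest["stages"][stage] = {
            "n_samples": int(tab.n_samples),
            "n_features": int(tab.n_features),
        }

    try:
        if table is None:
            if config.input_dir:
                log.info("reading study from %s", config.input_dir)
                table, phenotypes, truth = read_study(config.input_dir)
            else:
                log.info("simulating study with seed %d", config.seed)
                table, phenotypes, truth = generate_study(seed=config.seed)
                write_study(table, phenotypes, truth, outdir / "study")
        note("input", table)

        clean, reports = stage_preprocess(table, config)
        note("preprocessed", clean)
        reports_frame(reports).to_csv(outdir / "filter_report.csv", index=False)

        endo, exogenous, markers = stage_screen(clean, phenotypes, config)
        note("endogenous", endo)
        pd.DataFrame(
            [(g, f) for g, ids in exogenous.items() for f in ids],
            columns=["group", "feature_id"],
        ).to_csv(outdir / "exogenous_features.csv", index=False)
        markers.evidence.to_csv(outdir / "biomarkers.csv", index=False)
        if markers.spearman is not None:
            markers.spearman.to_csv(outdir / "spearman.csv", index=False)
        manifest["stages"]["markers"] = {
            "n_selected": len(markers.selected),
            "n_after_spearman": len(markers.selected),
        }

        pca, traj = stage_trajectory(endo, config)
        traj.table.to_csv(outdir / "trajectory.csv", index=False)
        manifest["stages"]["pca"] = {
            "r2x_2pc": float(np.sum(pca.explained_variance_ratio[:2])),
            "q2": float(pca.q2) if pca.q2 is not None else None,
        }

        curve, mds, auc_df, mds_tests = stage_mds(endo, markers.selected, config)
        mds.samples.rename_axis("sample_id").to_csv(outdir / "mds.csv")
        auc_df.to_csv(outdir / "mds_auc.csv", index=False)
        mds_tests.to_csv(outdir / "mds_tests.csv", index=False)
        manifest["stages"]["mds"] = {
            "curve_converged": bool(curve.converged),
            "curve_iterations": int(curve.n_iter),
        }

        curves, rauc_res, common = stage_rauc(endo, markers.selected, config)
        rauc_res.per_animal.to_csv(outdir / "rauc.csv", index=False)
        rauc_res.tests.to_csv(outdir / "rauc_tests.csv", index=False)
        pd.DataFrame(
            [(label, f) for label, ids in common.items() for f in ids],
            columns=["set_label", "feature_id"],
        ).to_csv(outdir / "rauc_common.csv", index=False)
    except Exception as exc:  # annotate which stage failed, then re-raise
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "input"
        log.error("pipeline aborted after stage %r: %s", stage, exc)
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "table": table,
        "phenotypes": phenotypes,
        "truth": truth,
        "preprocessed": clean,
        "reports": reports,
        "exogenous": exogenous,
        "markers": markers,
        "pca": pca,
        "trajectory": traj,
        "curve": curve,
        "mds": mds,
        "mds_auc": auc_df,
        "mds_tests": mds_tests,
        "rauc": rauc_res,
        "rauc_common": common,
        "manifest": manifest,
    }
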