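"""Peak-table reduction: background filtering, the 80% rule, QC stability
filtering, total-ion-intensity normalization, ion fusion and Pareto scaling.

All filters consume and return a :class:`~metaboeval.containers.PeakTable`
together with a :class:`~metaboeval.containers.FilterReport`; none of them
imputes missing values.  Conventions:

* a recorded 0 counts as observed; ``NaN`` is missing;
* a missing blank intensity is treated as 0 in the background ratio;
* the 80% rule counts study samples only (QCs/blanks excluded);
* QC relative standard deviation uses the n−1 sample standard deviation;
* Pareto scaling parameters are fit on study samples only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FilterReport, PeakTable


def _retain(table: PeakTable, keep_mask: pd.Series, stage: str):
    keep_ids = table.intensities.columns[keep_mask.to_numpy()]
    removed = table.intensities.columns[~keep_mask.to_numpy()]
    out = table.subset_features(keep_ids)
    report = FilterReport(
        stage=stage,
        n_in=table.n_features,
        n_removed=len(removed),
        n_retained=len(keep_ids),
        removed_ids=list(removed),
    )
    return out, report


def filter_background(table: PeakTable, min_sample_to_blank_ratio: float = 3.0):
    """Drop features whose study-sample signal is not well above blank signal.

    A feature is retained iff ``mean(study intensities, observed) >=
    ratio * mean(blank intensities, missing as 0)``.
    """
    if min_sample_to_blank_ratio <= 1:
        raise ValueError("min_sample_to_blank_ratio must exceed 1")
    if len(table.blank_ids) == 0:
        raise ValueError("background filtering requires at least one blank sample")
    if table.n_features == 0:
        return table.copy(), FilterReport("background", 0, 0, 0)
    study = table.intensities.loc[table.study_ids]
    blank = table.intensities.loc[table.blank_ids]
    sample_mean = study.mean(axis=0, skipna=True).fillna(0.0)
    blank_mean = blank.fillna(0.0).mean(axis=0)
    keep = sample_mean >= min_sample_to_blank_ratio * blank_mean
    return _retain(table, keep, "background")


def apply_80_rule(table: PeakTable, fraction: float = 0.8):
    """Retain features observed in >= ``fraction`` of samples of >=1 study group."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    meta = table.sample_meta
    study = meta.index[meta["sample_type"] == "study"]
    if len(study) == 0:
        raise ValueError("80% rule requires study samples")
    if table.n_features == 0:
        return table.copy(), FilterReport("rule80", 0, 0, 0)
    observed = table.intensities.loc[study].notna()
    groups = meta.loc[study, "group"]
    frac_by_group = observed.groupby(groups).mean()
    # tiny epsilon so that exactly 8/10 clears a 0.8 threshold under float noise
    keep = (frac_by_group.max(axis=0) >= fraction - 1e-12)
    return _retain(table, keep, "rule80")


def qc_rsd_filter(table: PeakTable, max_rsd: float = 0.15):
    """Retain features with QC relative standard deviation <= ``max_rsd``.

    Features observed in fewer than two QC injections are removed (their
    stability cannot be assessed).
    """
    qc_ids = table.qc_ids
    if len(qc_ids) < 2:
        raise ValueError("QC RSD filtering requires at least two QC samples")
    if table.n_features == 0:
        return table.copy(), FilterReport("qc_rsd", 0, 0, 0)
    qc = table.intensities.loc[qc_ids]
    n_obs = qc.notna().sum(axis=0)
    mean = qc.mean(axis=0, skipna=True)
    sd = qc.std(axis=0, ddof=1, skipna=True)
    rsd = sd / mean
    keep = (n_obs >= 2) & (mean > 0) & (rsd <= max_rsd)
    return _retain(table, keep.fillna(False), "qc_rsd")


def normalize_total_intensity(table: PeakTable) -> PeakTable:
    """Divide each sample row by its total observed intensity (rows sum to 1)."""
    totals = table.intensities.sum(axis=1, skipna=True)
    if (totals <= 0).any() or table.intensities.notna().sum(axis=1).eq(0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with non-positive total intensity: {bad[:5]}")
    out = table.copy()
    out.intensities = out.intensities.div(totals, axis=0)
    return out


def fuse_ions(table: PeakTable, feature_grouping=None, min_correlation: float = 0.9):
    """Merge redundant ions (adducts/isotopes) within declared windows.

    ``feature_grouping`` maps feature id → window label (dict or Series);
    features sharing a window are merged by single linkage on pairwise
    Pearson correlation (across study samples) at ``min_correlation``,
    keeping the first member's id and metadata and summing intensities.
    ``None`` disables fusion.
    """
    if not 0 < min_correlation <= 1:
        raise ValueError("min_correlation must be in (0, 1]")
    if feature_grouping is None or table.n_features == 0:
        return table.copy(), FilterReport(
            "ion_fusion", table.n_features, 0, table.n_features
        )
    grouping = pd.Series(feature_grouping)
    study = table.intensities.loc[table.study_ids]

    drop: list = []
    merged_into: dict = {}
    new_int = table.intensities.copy()
    for _, members in grouping.groupby(grouping):
        ids = [f for f in table.intensities.columns if f in set(members.index)]
        if len(ids) < 2:
            continue
        corr = study[ids].corr(method="pearson")
        # single-linkage components over the >= threshold graph
        parent = {f: f for f in ids}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, fi in enumerate(ids):
            for fj in ids[i + 1 :]:
                if corr.loc[fi, fj] >= min_correlation:
                    parent[find(fi)] = find(fj)
        clusters: dict = {}
        for f in ids:
            clusters.setdefault(find(f), []).append(f)
        for members_list in clusters.values():
            members_list = [f for f in ids if f in members_list]
            if len(members_list) < 2:
                continue
            head, rest = members_list[0], members_list[1:]
            block = table.intensities[members_list]
            summed = block.sum(axis=1, skipna=True)
            summed[block.notna().sum(axis=1) == 0] = np.nan
            new_int[head] = summed
            drop.extend(rest)
            for f in rest:
                merged_into[f] = head

    keep_cols = [f for f in table.intensities.columns if f not in set(drop)]
    out = PeakTable(
        new_int[keep_cols],
        table.sample_meta.copy(),
        table.feature_meta.loc[keep_cols].copy(),
    )
    report = FilterReport(
        "ion_fusion", table.n_features, len(drop), len(keep_cols), removed_ids=drop
    )
    report.merged_into = merged_into  # type: ignore[attr-defined]
    return out, report


def pareto_scale(matrix):
    """Centre columns and divide by the square root of their standard deviation.

    Returns ``(scaled, means, sds)``.  After scaling each column has mean 0
    and variance equal to its original standard deviation.  Raises on a
    constant column.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("Pareto scaling requires at least two rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        if is_frame:
            bad = matrix.columns[sds == 0].tolist()
        else:
            bad = np.flatnonzero(sds == 0).tolist()
        raise ValueError(f"constant columns cannot be Pareto scaled: {bad[:5]}")
    scaled = (X - means) / np.sqrt(sds)
    if is_frame:
        scaled = pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)
        means = pd.Series(means, index=matrix.columns)
        sds = pd.Series(sds, index=matrix.columns)
    return scaled, means, sds


def impute_half_minimum(table: PeakTable) -> PeakTable:
    """Fill missing cells with half the feature's minimum observed intensity.

    An explicit modelling step (standard left-censoring surrogate), kept
    outside the filter chain: no filter above ever imputes.  Features with
    no observed value at all are filled with 0.
    """
    out = table.copy()
    mins = out.intensities.min(axis=0, skipna=True)
    fill = (mins / 2.0).fillna(0.0)
    out.intensities = out.intensities.fillna(fill)
    return out
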