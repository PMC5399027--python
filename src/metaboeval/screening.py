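"""Exogenous-feature removal and discriminating-metabolite selection.

Decoction-originated (exogenous) compounds are detected against the pooled
control + toxin-only ("CT") reference: an OPLS-DA model of treated vs CT
ranks candidates by |p(corr)|, and a feature is called exogenous when it
is essentially absent from CT while consistently present in the treated
group.  Only post-baseline samples enter the presence counts, since dosing
starts after the baseline bleed.

Biomarker selection then runs per time point between the toxin group and
every other group: OPLS-DA VIP > 1.0 combined with a BH-adjusted
Mann–Whitney p < 0.05.  The union over comparisons is finally filtered by
Spearman correlation (|rho| >= 0.5 against diarrhea score or relative body
weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .containers import PeakTable, validate_phenotypes
from .multivariate import fit_oplsda, s_plot, select_n_orth
from .preprocessing import impute_half_minimum, pareto_scale


@dataclass
class BiomarkerSet:
    """Selected features plus the per-comparison and per-phenotype evidence."""

    selected: list
    evidence: pd.DataFrame  # feature_id, comparison, day, vip, p_raw, p_adj, selected
    spearman: pd.DataFrame | None = None  # feature_id, rho_ds, rho_rbw, retained
    removed: dict = field(default_factory=dict)  # feature_id -> reason


def _model_matrix(table: PeakTable, sample_ids) -> pd.DataFrame:
    """Complete, Pareto-scalable submatrix for the given samples.

    Missing cells get the half-minimum fill; constant columns are dropped
    (they carry no discriminative information for these samples).
    """
    sub = table.subset_samples(sample_ids)
    filled = impute_half_minimum(sub).intensities
    sds = filled.std(axis=0, ddof=1)
    keep = sds[sds > 0].index
    scaled, _, _ = pareto_scale(filled[keep])
    return scaled


def detect_exogenous(
    table: PeakTable,
    treated_group,
    control_group="C",
    toxin_group="T",
    absence_fraction: float = 0.1,
    n_orth: int = 1,
) -> list:
    """Feature ids of decoction-only compounds for one treated group.

    Flag rule: observed in < ``absence_fraction`` of post-baseline CT
    samples while observed in >= ``1 - absence_fraction`` of post-baseline
    treated samples.  Returned sorted by decreasing |p(corr)| in the
    treated-vs-CT OPLS-DA model.
    """
    if not 0 < absence_fraction < 0.5:
        raise ValueError("absence_fraction must be in (0, 0.5)")
    meta = table.sample_meta
    baseline = meta.loc[table.study_ids, "day"].min()
    post = (meta["sample_type"] == "study") & (meta["day"] > baseline)
    ct_ids = meta.index[post & meta["group"].isin([control_group, toxin_group])]
    tr_ids = meta.index[post & (meta["group"] == treated_group)]
    if len(ct_ids) == 0 or len(tr_ids) == 0:
        raise ValueError("empty CT or treated group")

    obs = table.intensities.notna()
    frac_ct = obs.loc[ct_ids].mean(axis=0)
    frac_tr = obs.loc[tr_ids].mean(axis=0)
    flagged = table.intensities.columns[
        (frac_ct < absence_fraction) & (frac_tr >= 1.0 - absence_fraction)
    ]
    if len(flagged) == 0:
        return []

    # rank flagged candidates by |pcorr| with the treated-vs-CT predictive score
    ids = ct_ids.append(tr_ids)
    X = _model_matrix(table, ids)
    y = np.where(meta.loc[ids, "group"] == treated_group, "treated", "ct")
    model = fit_oplsda(X, y, n_orth=n_orth, positive_class="treated")
    splot = s_plot(model, X)
    ranked = splot["pcorr"].abs().sort_values(ascending=False)
    order = {f: i for i, f in enumerate(ranked.index)}
    return sorted(flagged, key=lambda f: order.get(f, len(order)))


def remove_features(table: PeakTable, ids) -> PeakTable:
    """Drop the given feature columns; sample set unchanged."""
    return table.drop_features(ids)


def select_biomarkers(
    table: PeakTable,
    toxin_group,
    other_group,
    day,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    use_adjusted_p: bool = True,
    n_orth: int | None = None,
    cv_seed: int = 0,
) -> pd.DataFrame:
    """Marker records for one toxin-vs-other comparison at one day.

    Fits OPLS-DA between the two groups at that day, Mann–Whitney tests
    every feature, BH-adjusts within the comparison, and flags markers
    with VIP > ``vip_threshold`` and (adjusted) p < ``p_threshold``.
    ``n_orth=None`` selects the orthogonal component count by
    cross-validation.
    """
    a_ids = table.group_sample_ids(toxin_group, day)
    b_ids = table.group_sample_ids(other_group, day)
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise ValueError(f"group absent at day {day}")
    ids = a_ids.append(b_ids)
    X = _model_matrix(table, ids)
    y = np.where(
        table.sample_meta.loc[ids, "group"] == toxin_group, "toxin", "other"
    )
    if n_orth is None:
        n_orth = select_n_orth(X, y, max_orth=2, seed=cv_seed)
    model = fit_oplsda(X, y, n_orth=n_orth, positive_class="toxin")
    vip = pd.Series(model.vip, index=X.columns)

    raw_int = table.intensities
    p_raw = {}
    for f in X.columns:
        xa = raw_int.loc[a_ids, f].dropna().to_numpy()
        xb = raw_int.loc[b_ids, f].dropna().to_numpy()
        if xa.size == 0 or xb.size == 0:
            p_raw[f] = 1.0
        else:
            p_raw[f] = stats.mann_whitney(xa, xb).p_value
    p_raw = pd.Series(p_raw)
    p_adj = pd.Series(stats.bh_fdr(p_raw.to_numpy()), index=p_raw.index)
    p_used = p_adj if use_adjusted_p else p_raw
    selected = (vip > vip_threshold) & (p_used < p_threshold)
    return pd.DataFrame(
        {
            "feature_id": X.columns,
            "comparison": f"{toxin_group}_vs_{other_group}",
            "day": day,
            "vip": vip.to_numpy(),
            "p_raw": p_raw.to_numpy(),
            "p_adj": p_adj.to_numpy(),
            "selected": selected.to_numpy(),
        }
    )


def union_biomarkers(records: list) -> BiomarkerSet:
    """Union of selected markers over all comparisons, keeping every record."""
    if not records:
        raise ValueError("no comparison records given")
    evidence = pd.concat(records, ignore_index=True)
    selected = sorted(evidence.loc[evidence["selected"], "feature_id"].unique())
    return BiomarkerSet(selected=selected, evidence=evidence)


def spearman_filter(
    bset: BiomarkerSet,
    table: PeakTable,
    phenotypes: pd.DataFrame,
    cutoff: float = 0.5,
) -> BiomarkerSet:
    """Drop markers weakly correlated with both phenotypes.

    Each study sample's intensity is paired with its own animal's same-day
    diarrhea score and relative body weight; a marker survives iff
    |rho| >= ``cutoff`` against at least one phenotype.
    """
    phenotypes = validate_phenotypes(phenotypes)
    meta = table.sample_meta.loc[table.study_ids, ["animal_id", "day"]].reset_index()
    merged = meta.merge(phenotypes, on=["animal_id", "day"], how="inner")
    if merged.empty:
        raise ValueError("no sample matches any (animal, day) phenotype row")
    sample_ids = merged["sample_id"] if "sample_id" in merged else merged.iloc[:, 0]

    rows = []
    removed = dict(bset.removed)
    retained = []
    for f in bset.selected:
        x = table.intensities.loc[sample_ids, f].to_numpy()
        ok = ~np.isnan(x)
        rho_ds = stats.spearman_rho(x[ok], merged.loc[ok, "ds"].to_numpy())
        rho_rbw = stats.spearman_rho(x[ok], merged.loc[ok, "rbw"].to_numpy())
        keep = max(abs(rho_ds), abs(rho_rbw)) >= cutoff
        rows.append(
            {"feature_id": f, "rho_ds": rho_ds, "rho_rbw": rho_rbw, "retained": keep}
        )
        if keep:
            retained.append(f)
        else:
            removed[f] = f"weak phenotype correlation (|rho| < {cutoff})"
    spearman = pd.DataFrame(rows)
    return BiomarkerSet(
        selected=retained, evidence=bset.evidence, spearman=spearman, removed=removed
    )
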