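"""Relative fold-change curves and their areas (RAUC).

For each selected metabolite, every animal's level at each window day is
expressed relative to the same-day control-group mean — log2(x / control
mean), so the control sits at 0 by construction.  RAUC is the trapezoidal
area of the |relative level| curve over the delayed-toxicity window
(default days 4–10); lower RAUC means closer to control.  Treated groups
are compared against the toxin-only group per metabolite with unadjusted
Mann–Whitney tests, and a metabolite is called *re-regulated* in a group
when its RAUC is significantly lower there than in the toxin group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .containers import PeakTable


@dataclass
class RaucResult:
    per_animal: pd.DataFrame  # animal_id, group, feature_id, rauc
    group_summary: pd.DataFrame  # group, feature_id, median_rauc
    tests: pd.DataFrame  # group, feature_id, U, p, reregulated
    toxin_group: object
    alpha: float


def relative_curves(
    table: PeakTable,
    control_group,
    metabolites,
    window_days=None,
    scale: str = "log2",
) -> pd.DataFrame:
    """Long frame (animal_id, group, feature_id, day, rel_level).

    ``scale="log2"`` gives log2(x / control mean); ``"fc"`` gives
    x / control mean − 1.  Missing intensities are filled with half the
    metabolite's minimum observed value before forming ratios.
    """
    if scale not in ("log2", "fc"):
        raise ValueError("scale must be 'log2' or 'fc'")
    metabolites = list(metabolites)
    unknown = set(metabolites) - set(table.intensities.columns)
    if unknown:
        raise KeyError(f"unknown metabolites: {sorted(unknown)[:5]}")
    meta = table.sample_meta
    study = table.study_ids
    days = sorted(meta.loc[study, "day"].unique())
    if window_days is not None:
        lo, hi = min(window_days), max(window_days)
        days = [d for d in days if lo <= d <= hi]
    if len(days) < 2:
        raise ValueError("window must contain at least two sampled days")

    intens = table.intensities.loc[study, metabolites]
    mins = intens.min(axis=0, skipna=True)
    intens = intens.fillna(mins / 2.0)
    if (intens <= 0).any().any():
        raise ValueError("non-positive intensities for the requested metabolites")
    smeta = meta.loc[study]

    rows = []
    for d in days:
        day_ids = smeta.index[smeta["day"] == d]
        ctrl_ids = smeta.index[(smeta["day"] == d) & (smeta["group"] == control_group)]
        if len(ctrl_ids) == 0:
            raise ValueError(f"control group not sampled at day {d}")
        ctrl_mean = intens.loc[ctrl_ids].mean(axis=0)
        if (ctrl_mean <= 0).any():
            raise ValueError(f"zero control mean at day {d}")
        ratio = intens.loc[day_ids].div(ctrl_mean, axis=1)
        rel = np.log2(ratio) if scale == "log2" else ratio - 1.0
        block = rel.stack().rename("rel_level").reset_index()
        block.columns = ["sample_id", "feature_id", "rel_level"]
        block["animal_id"] = smeta.loc[block["sample_id"], "animal_id"].to_numpy()
        block["group"] = smeta.loc[block["sample_id"], "group"].to_numpy()
        block["day"] = d
        rows.append(block[["animal_id", "group", "feature_id", "day", "rel_level"]])
    return pd.concat(rows, ignore_index=True)


def compute_rauc(
    curves: pd.DataFrame, toxin_group="T", alpha: float = 0.05
) -> RaucResult:
    """Trapezoidal |relative level| areas and group-vs-toxin tests.

    P-values are deliberately unadjusted (per-metabolite screening
    convention); the re-regulation call additionally requires the group's
    median RAUC to lie below the toxin group's.
    """
    required = {"animal_id", "group", "feature_id", "day", "rel_level"}
    if not required <= set(curves.columns):
        raise ValueError(f"curves frame lacks {sorted(required - set(curves.columns))}")
    rows = []
    for (animal, group, feat), adf in curves.groupby(
        ["animal_id", "group", "feature_id"], sort=True
    ):
        adf = adf.sort_values("day")
        if adf.shape[0] < 2:
            raise ValueError(f"animal {animal} has a single-day curve for {feat}")
        area = stats.trapezoid_auc(
            np.abs(adf["rel_level"].to_numpy()), adf["day"].to_numpy()
        )
        rows.append(
            {"animal_id": animal, "group": group, "feature_id": feat, "rauc": area}
        )
    per_animal = pd.DataFrame(rows)
    group_summary = (
        per_animal.groupby(["group", "feature_id"])["rauc"]
        .median()
        .rename("median_rauc")
        .reset_index()
    )
    if toxin_group not in set(per_animal["group"]):
        raise ValueError(f"toxin group {toxin_group!r} absent from the curves")

    tests = []
    tox = per_animal[per_animal["group"] == toxin_group]
    for group in sorted(set(per_animal["group"]) - {toxin_group}):
        sub = per_animal[per_animal["group"] == group]
        for feat in sorted(sub["feature_id"].unique()):
            xg = sub.loc[sub["feature_id"] == feat, "rauc"].to_numpy()
            xt = tox.loc[tox["feature_id"] == feat, "rauc"].to_numpy()
            res = stats.mann_whitney(xg, xt)
            lower = np.median(xg) < np.median(xt)
            tests.append(
                {
                    "group": group,
                    "feature_id": feat,
                    "U": res.statistic,
                    "p": res.p_value,
                    "reregulated": bool(res.p_value < alpha and lower),
                }
            )
    return RaucResult(
        per_animal=per_animal,
        group_summary=group_summary,
        tests=pd.DataFrame(tests),
        toxin_group=toxin_group,
        alpha=alpha,
    )


def common_reregulated(result: RaucResult, group_sets: dict) -> dict:
    """Metabolites re-regulated in *every* group of each requested set."""
    out = {}
    tests = result.tests
    for label, groups in group_sets.items():
        groups = list(groups)
        if len(groups) < 2:
            raise ValueError(f"group set {label!r} needs at least two groups")
        sets = []
        for g in groups:
            sub = tests[(tests["group"] == g) & tests["reregulated"]]
            sets.append(set(sub["feature_id"]))
        out[label] = sorted(set.intersection(*sets)) if sets else []
    return out
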