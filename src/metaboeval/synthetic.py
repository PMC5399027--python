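"""Synthetic six-group time-course serum metabolomics study.

Emulates a rodent toxicity/rescue design: a control group, a toxin-only
group whose metabolome is perturbed with a peak at day 4 and near-complete
recovery by day 10, and treated groups in which the perturbation is
attenuated to a graded degree.  The generator returns a peak table
(study + pooled-QC + blank injections), a per-animal phenotype series
(diarrhea score and relative body weight, both monotone in the true
deregulation), and full ground truth for every downstream stage.

Model: log2 intensity = feature baseline + animal×feature random effect +
signed effect × day profile × group attenuation + residual noise.
Intensities below the detection limit are left-censored to missing;
decoction-only (exogenous) features exist only in a treated group's
post-dosing samples; background features appear in blanks at full
strength.  One integer seed drives a single generator stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PeakTable, validate_phenotypes

DEFAULT_GROUPS = ("C", "T", "T/HQD", "T/SS", "T/BB", "T/SF")
DEFAULT_COUNTS = (10, 11, 12, 10, 10, 10)
DEFAULT_DAYS = (-1, 1, 4, 7, 10)

#: toxin effect multiplier per day: onset day 1, peak day 4, recovery 7-10
DEFAULT_EFFECT_PROFILE = {-1: 0.0, 1: 0.6, 4: 1.0, 7: 0.25, 10: 0.05}

#: fraction of the full toxin effect remaining under each regimen
DEFAULT_ATTENUATION = {
    "C": 0.0,
    "T": 1.0,
    "T/HQD": 0.2,
    "T/SS": 0.35,
    "T/BB": 0.55,
    "T/SF": 0.75,
}

PLATFORMS = ("lcms_pos", "lcms_neg", "gcms")


@dataclass
class StudyDesign:
    """Group labels, animal counts, sampling days and QC/blank injections."""

    groups: tuple = DEFAULT_GROUPS
    n_per_group: tuple = DEFAULT_COUNTS
    days: tuple = DEFAULT_DAYS
    n_qc: int = 10
    n_blank: int = 4
    control_group: str = "C"
    toxin_group: str = "T"

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.n_per_group):
            raise ValueError("groups and n_per_group lengths differ")
        if any(n < 1 for n in self.n_per_group) or self.n_qc < 1 or self.n_blank < 1:
            raise ValueError("all counts must be >= 1")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        for label, name in ((self.control_group, "control"), (self.toxin_group, "toxin")):
            if label not in self.groups:
                raise ValueError(f"{name} group {label!r} not among groups")
        if self.control_group == self.toxin_group:
            raise ValueError("control and toxin groups must differ")

    @property
    def baseline_day(self):
        return min(self.days)

    @property
    def n_animals(self) -> int:
        return int(sum(self.n_per_group))


@dataclass
class PerturbationSpec:
    """Effect structure planted in the synthetic study.

    ``effect_size_sd`` is the peak (day-4) log2 effect magnitude expressed
    in multiples of the total residual log2 SD (animal + noise), so "a
    1.5-SD effect" is literally ``effect_size_sd=1.5``.
    """

    n_features_total: int = 200
    n_perturbed: int = 40
    effect_profile: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_PROFILE))
    group_attenuation: dict = field(default_factory=lambda: dict(DEFAULT_ATTENUATION))
    n_exogenous_per_group: int = 8
    n_background: int = 15
    effect_size_sd: float = 4.5
    noise_sd: float = 0.4
    animal_sd: float = 0.25
    qc_noise_sd: float = 0.1
    missing_rate: float = 0.3
    lod_log2: float = 9.0
    baseline_log2_range: tuple = (9.5, 16.0)
    # perturb only mid/high-abundance features: keeps the total ion current
    # composition-stable (as in real serum, where the TIC is carried by
    # abundant stable peaks) and keeps biomarkers clear of the detection
    # limit over their whole deregulation range, so down-regulation is
    # measured rather than censored
    perturb_min_baseline_log2: float = 13.0
    #: per-feature multiplicative jitter on the effect magnitude
    effect_jitter: tuple = (0.7, 1.3)
    ds_noise: float = 0.25
    rbw_drop: float = 30.0
    rbw_noise: float = 1.5

    def validate(self, design: StudyDesign) -> None:
        if self.n_perturbed > self.n_features_total:
            raise ValueError("n_perturbed exceeds n_features_total")
        if min(self.n_features_total, self.n_perturbed) < 0:
            raise ValueError("negative feature counts")
        att = self.group_attenuation
        for g in design.groups:
            if g not in att:
                raise ValueError(f"no attenuation for group {g!r}")
            if not 0.0 <= att[g] <= 1.0:
                raise ValueError(f"attenuation for {g!r} outside [0, 1]")
        if att[design.control_group] != 0.0:
            raise ValueError("control attenuation must be 0")
        if att[design.toxin_group] != 1.0:
            raise ValueError("toxin-only attenuation must be 1")
        if self.effect_profile.get(design.baseline_day, 0.0) != 0.0:
            raise ValueError("effect profile must vanish at the baseline day")
        for d in design.days:
            if d not in self.effect_profile:
                raise ValueError(f"effect profile missing day {d}")

    @property
    def residual_sd(self) -> float:
        return float(np.hypot(self.animal_sd, self.noise_sd))


@dataclass
class GroundTruth:
    """What was planted: perturbed/exogenous/background ids and magnitudes."""

    perturbed_feature_ids: list
    exogenous_feature_ids: dict  # treated group -> list of feature ids
    background_feature_ids: list
    effect_log2: dict  # perturbed feature id -> signed peak log2 effect
    deregulation: pd.Series  # sample id -> true deregulation magnitude in [0, 1]
    attenuation: dict
    effect_profile: dict

    def all_exogenous(self) -> list:
        out: list = []
        for ids in self.exogenous_feature_ids.values():
            out.extend(ids)
        return sorted(out)


def generate_study(
    design: StudyDesign | None = None,
    spec: PerturbationSpec | None = None,
    seed: int = 0,
):
    """Generate ``(PeakTable, phenotype DataFrame, GroundTruth)``.

    Bit-for-bit reproducible for a fixed seed: all randomness flows from a
    single ``numpy.random.default_rng(seed)`` stream.
    """
    design = design or StudyDesign()
    spec = spec or PerturbationSpec()
    spec.validate(design)
    rng = np.random.default_rng(seed)

    # ---- feature catalogue
    n_endo = spec.n_features_total
    endo_ids = [f"M{i:04d}" for i in range(1, n_endo + 1)]
    bg_ids = [f"B{i:03d}" for i in range(1, spec.n_background + 1)]
    treated = [
        g
        for g in design.groups
        if g not in (design.control_group, design.toxin_group)
    ]
    exo_ids: dict = {}
    for g in treated:
        tag = "".join(ch for ch in g if ch.isalnum())
        exo_ids[g] = [
            f"X{tag}{i:02d}" for i in range(1, spec.n_exogenous_per_group + 1)
        ]
    all_exo = [f for g in treated for f in exo_ids[g]]
    feature_ids = endo_ids + bg_ids + all_exo
    n_feat = len(feature_ids)

    platforms = rng.choice(PLATFORMS, size=n_feat)
    feature_meta = pd.DataFrame(
        {
            "platform": platforms,
            "is_background": [f in set(bg_ids) for f in feature_ids],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    baselines = rng.uniform(*spec.baseline_log2_range, size=n_feat)
    base = pd.Series(baselines, index=feature_ids)
    # exogenous compounds and background contaminants sit at solid
    # mid-range intensity when present
    for f in all_exo:
        base[f] = rng.uniform(12.0, 16.0)
    for f in bg_ids:
        base[f] = rng.uniform(12.0, 16.0)

    eligible = [f for f in endo_ids if base[f] >= spec.perturb_min_baseline_log2]
    if len(eligible) < spec.n_perturbed:
        raise ValueError(
            "too few features above perturb_min_baseline_log2 to perturb"
        )
    perturbed = sorted(
        rng.choice(eligible, size=spec.n_perturbed, replace=False).tolist()
    )
    delta = spec.effect_size_sd * spec.residual_sd
    signs = rng.choice([-1.0, 1.0], size=spec.n_perturbed)
    mags = rng.uniform(*spec.effect_jitter, size=spec.n_perturbed)
    effect_log2 = {
        f: float(s * m * delta) for f, s, m in zip(perturbed, signs, mags)
    }

    # ---- study samples
    col_of = {f: j for j, f in enumerate(feature_ids)}
    pert_idx = np.array([col_of[f] for f in perturbed], dtype=int)
    pert_delta = np.array([effect_log2[f] for f in perturbed])
    exo_idx = {g: np.array([col_of[f] for f in ids], dtype=int) for g, ids in exo_ids.items()}
    rows, meta_rows = [], []
    dereg_vals, dereg_ids = [], []
    pheno_rows = []
    animal_effects: dict = {}
    for g, n_animals in zip(design.groups, design.n_per_group):
        att = spec.group_attenuation[g]
        for a in range(1, n_animals + 1):
            animal = f"{g}-{a:02d}".replace("/", "")
            animal_effects[animal] = rng.normal(0.0, spec.animal_sd, size=n_feat)
            for day in design.days:
                m = att * spec.effect_profile[day]
                sid = f"{animal}_d{day}"
                log2x = base.to_numpy().copy()
                log2x += animal_effects[animal]
                log2x += rng.normal(0.0, spec.noise_sd, size=n_feat)
                if m > 0:
                    log2x[pert_idx] += m * pert_delta
                # exogenous: present only in this group's post-dosing samples
                for tg, idxs in exo_idx.items():
                    if not (g == tg and day > design.baseline_day):
                        log2x[idxs] = -np.inf  # absent compound
                rows.append(log2x)
                meta_rows.append((sid, g, animal, day, "study"))
                dereg_ids.append(sid)
                dereg_vals.append(m)
            # phenotype per animal-day
            for day in design.days:
                m = att * spec.effect_profile[day]
                ds = float(np.clip(3.0 * m + rng.normal(0, spec.ds_noise), 0.0, 3.0))
                rbw = float(100.0 - spec.rbw_drop * m + rng.normal(0, spec.rbw_noise))
                pheno_rows.append((animal, day, ds, rbw))

    study_log2 = np.vstack(rows)

    # ---- QC samples: pooled aliquot of all study samples, low analytical noise
    with np.errstate(over="ignore"):
        study_lin = np.where(np.isfinite(study_log2), 2.0**study_log2, 0.0)
    pool = study_lin.mean(axis=0)
    qc_rows = []
    for q in range(1, design.n_qc + 1):
        noise = rng.normal(0.0, spec.qc_noise_sd, size=n_feat)
        qc_rows.append(np.where(pool > 0, np.log2(np.maximum(pool, 1e-12)) + noise, -np.inf))
        meta_rows.append((f"QC{q:02d}", "QC", "QC", design.baseline_day, "qc"))
    # ---- blanks: background features only
    blank_rows = []
    bg_idx = [col_of[f] for f in bg_ids]
    for b in range(1, design.n_blank + 1):
        row = np.full(n_feat, -np.inf)
        row[bg_idx] = base.to_numpy()[bg_idx] + rng.normal(
            0.0, spec.noise_sd, size=len(bg_idx)
        )
        blank_rows.append(row)
        meta_rows.append((f"BL{b:02d}", "BLANK", "BLANK", design.baseline_day, "blank"))

    log2_all = np.vstack([study_log2] + [np.vstack(qc_rows)] + [np.vstack(blank_rows)])

    # ---- left-censoring to missing
    with np.errstate(over="ignore"):
        lin = np.where(np.isfinite(log2_all), 2.0**log2_all, 0.0)
    below_lod = log2_all < spec.lod_log2
    low_band = (log2_all >= spec.lod_log2) & (log2_all < spec.lod_log2 + 1.0)
    drop_low = rng.random(log2_all.shape) < spec.missing_rate
    lin[below_lod] = np.nan
    lin[low_band & drop_low] = np.nan

    sample_ids = [r[0] for r in meta_rows]
    sample_meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "group", "animal_id", "day", "sample_type"],
    ).set_index("sample_id")
    intensities = pd.DataFrame(
        lin, index=pd.Index(sample_ids, name="sample_id"), columns=feature_ids
    )
    table = PeakTable(intensities, sample_meta, feature_meta)

    phenotypes = validate_phenotypes(
        pd.DataFrame(pheno_rows, columns=["animal_id", "day", "ds", "rbw"])
    )
    truth = GroundTruth(
        perturbed_feature_ids=perturbed,
        exogenous_feature_ids=exo_ids,
        background_feature_ids=bg_ids,
        effect_log2=effect_log2,
        deregulation=pd.Series(dereg_vals, index=pd.Index(dereg_ids, name="sample_id")),
        attenuation=dict(spec.group_attenuation),
        effect_profile=dict(spec.effect_profile),
    )
    return table, phenotypes, truth


# ---------------------------------------------------------------- I/O


def write_study(table: PeakTable, phenotypes: pd.DataFrame, truth: GroundTruth | None,
                directory) -> dict:
    """Write the study to CSV files (+ truth.json); missing cells are empty."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": directory / "intensities.csv",
        "samples": directory / "samples.csv",
        "features": directory / "features.csv",
        "phenotype": directory / "phenotype.csv",
    }
    table.intensities.to_csv(paths["intensities"])
    table.sample_meta.to_csv(paths["samples"])
    table.feature_meta.to_csv(paths["features"])
    phenotypes.to_csv(paths["phenotype"], index=False)
    if truth is not None:
        paths["truth"] = directory / "truth.json"
        payload = {
            "perturbed_feature_ids": truth.perturbed_feature_ids,
            "exogenous_feature_ids": truth.exogenous_feature_ids,
            "background_feature_ids": truth.background_feature_ids,
            "effect_log2": truth.effect_log2,
            "deregulation": truth.deregulation.to_dict(),
            "attenuation": truth.attenuation,
            "effect_profile": {str(k): v for k, v in truth.effect_profile.items()},
        }
        paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}


def read_study(directory):
    """Read a study written by :func:`write_study`.

    Returns ``(PeakTable, phenotypes, truth-or-None)``.  Raises on
    duplicated sample ids, misaligned metadata or unknown sample types.
    """
    directory = Path(directory)
    raw = pd.read_csv(directory / "intensities.csv", index_col=0)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids in intensities.csv: {dups}")
    sample_meta = pd.read_csv(directory / "samples.csv", index_col=0)
    feature_meta = pd.read_csv(directory / "features.csv", index_col=0)
    table = PeakTable(raw, sample_meta, feature_meta)
    phenotypes = validate_phenotypes(pd.read_csv(directory / "phenotype.csv"))
    truth = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        truth = GroundTruth(
            perturbed_feature_ids=payload["perturbed_feature_ids"],
            exogenous_feature_ids=payload["exogenous_feature_ids"],
            background_feature_ids=payload["background_feature_ids"],
            effect_log2=payload["effect_log2"],
            deregulation=pd.Series(payload["deregulation"]).rename_axis("sample_id"),
            attenuation=payload["attenuation"],
            effect_profile={int(k): v for k, v in payload["effect_profile"].items()},
        )
    return table, phenotypes, truth
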