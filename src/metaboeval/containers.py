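"""Central in-memory containers for the pipeline.

A :class:`PeakTable` couples a samples × features intensity matrix with
sample metadata (group, animal, day, sample type) and feature metadata
(platform, background flag).  Missing values are ``NaN``; a recorded zero
is an *observed* zero, absence of a peak is missing.  Every pipeline stage
consumes and returns this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("study", "qc", "blank")

#: required columns of the sample metadata frame (index: sample_id)
SAMPLE_META_COLUMNS = ("group", "animal_id", "day", "sample_type")


@dataclass
class PeakTable:
    """Samples × features intensity matrix plus metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id with feature ids as columns.
        Non-negative where observed; ``NaN`` encodes a missing peak.
    sample_meta
        DataFrame indexed by sample id with columns ``group``,
        ``animal_id``, ``day`` and ``sample_type`` (study/qc/blank).
    feature_meta
        DataFrame indexed by feature id with at least a ``platform``
        column (``lcms_pos``, ``lcms_neg`` or ``gcms``).
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------
    def validate(self) -> None:
        idx = self.intensities.index
        cols = self.intensities.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if not idx.equals(self.sample_meta.index):
            missing = idx.difference(self.sample_meta.index).tolist()
            extra = self.sample_meta.index.difference(idx).tolist()
            raise ValueError(
                f"sample metadata misaligned (missing={missing[:5]}, extra={extra[:5]})"
            )
        if not cols.equals(self.feature_meta.index):
            raise ValueError("feature metadata misaligned with intensity columns")
        for c in SAMPLE_META_COLUMNS:
            if c not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {c!r}")
        bad = set(self.sample_meta["sample_type"]) - set(SAMPLE_TYPES)
        if bad:
            raise ValueError(f"unknown sample_type values: {sorted(bad)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative where observed")

    # -- basic shape ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    # -- masks ------------------------------------------------------
    def _type_ids(self, kind: str) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["sample_type"] == kind]

    @property
    def study_ids(self) -> pd.Index:
        return self._type_ids("study")

    @property
    def qc_ids(self) -> pd.Index:
        return self._type_ids("qc")

    @property
    def blank_ids(self) -> pd.Index:
        return self._type_ids("blank")

    @property
    def groups(self) -> list:
        meta = self.sample_meta.loc[self.study_ids]
        return sorted(meta["group"].unique().tolist())

    @property
    def days(self) -> list:
        meta = self.sample_meta.loc[self.study_ids]
        return sorted(meta["day"].unique().tolist())

    def group_sample_ids(self, group, day=None) -> pd.Index:
        meta = self.sample_meta
        mask = (meta["sample_type"] == "study") & (meta["group"] == group)
        if day is not None:
            mask &= meta["day"] == day
        return meta.index[mask]

    # -- subsetting -------------------------------------------------
    def subset_samples(self, ids) -> "PeakTable":
        ids = pd.Index(ids)
        unknown = ids.difference(self.intensities.index)
        if len(unknown):
            raise KeyError(f"unknown sample ids: {unknown.tolist()[:5]}")
        return PeakTable(
            self.intensities.loc[ids].copy(),
            self.sample_meta.loc[ids].copy(),
            self.feature_meta.copy(),
        )

    def subset_features(self, ids) -> "PeakTable":
        ids = pd.Index(ids)
        unknown = ids.difference(self.intensities.columns)
        if len(unknown):
            raise KeyError(f"unknown feature ids: {unknown.tolist()[:5]}")
        return PeakTable(
            self.intensities.loc[:, ids].copy(),
            self.sample_meta.copy(),
            self.feature_meta.loc[ids].copy(),
        )

    def drop_features(self, ids) -> "PeakTable":
        ids = pd.Index(ids)
        unknown = ids.difference(self.intensities.columns)
        if len(unknown):
            raise KeyError(f"unknown feature ids: {unknown.tolist()[:5]}")
        keep = self.intensities.columns.difference(ids, sort=False)
        return self.subset_features(keep)

    def copy(self) -> "PeakTable":
        return PeakTable(
            self.intensities.copy(), self.sample_meta.copy(), self.feature_meta.copy()
        )

    def study_matrix(self) -> pd.DataFrame:
        """Intensity rows of study samples only (QCs and blanks dropped)."""
        return self.intensities.loc[self.study_ids]

    def equals(self, other: "PeakTable") -> bool:
        return (
            self.intensities.equals(other.intensities)
            and self.sample_meta.equals(other.sample_meta)
            and self.feature_meta.equals(other.feature_meta)
        )


@dataclass
class FilterReport:
    """One preprocessing stage's bookkeeping: rule name and feature counts."""

    stage: str
    n_in: int
    n_removed: int
    n_retained: int
    removed_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_removed + self.n_retained != self.n_in:
            raise ValueError(
                f"{self.stage}: removed ({self.n_removed}) + retained "
                f"({self.n_retained}) != input ({self.n_in})"
            )

    def to_row(self) -> dict:
        return {
            "stage": self.stage,
            "n_in": self.n_in,
            "removed": self.n_removed,
            "retained": self.n_retained,
        }


def reports_frame(reports) -> pd.DataFrame:
    """Stack stage reports into the serializable (stage, removed, retained) table."""
    return pd.DataFrame([r.to_row() for r in reports])


def validate_phenotypes(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype series frame (animal_id, day, ds, rbw).

    DS is the diarrhea score on the 0–3 scale; RBW is body weight relative
    to the baseline day in percent (must be positive).
    """
    required = {"animal_id", "day", "ds", "rbw"}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype frame lacks columns {sorted(missing)}")
    if ((phenotypes["ds"] < 0) | (phenotypes["ds"] > 3)).any():
        raise ValueError("diarrhea score outside the 0-3 scale")
    if (phenotypes["rbw"] <= 0).any():
        raise ValueError("relative body weight must be positive")
    if phenotypes.duplicated(["animal_id", "day"]).any():
        raise ValueError("duplicate (animal_id, day) phenotype rows")
    return phenotypes
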