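"""Global deregulation quantification.

Two instruments:

* **PCA trajectory** — per-group, per-day means of PC1/PC2 and each
  group's Euclidean displacement from its own baseline day, visualising
  the perturbation-and-recovery arc in score space.

* **Metabolites Deregulation Score (MDS)** — a Hastie–Stuetzle principal
  curve is fitted through the biomarker matrix in a reduced PCA space;
  every sample is projected onto the curve and scored by its normalized
  arc-length position, oriented so the healthy (control) end is 0.  A
  sample's MDS in [0, 1] measures how far along the deregulation axis it
  sits; per-animal MDS-vs-day areas (trapezoid) summarise whole-course
  deviation, compared between groups by Mann–Whitney tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .multivariate import fit_pca


# ------------------------------------------------------------ trajectory


@dataclass
class Trajectory:
    table: pd.DataFrame  # group, day, pc1, pc2, displacement


def compute_trajectory(pca, sample_meta: pd.DataFrame) -> Trajectory:
    """Group-day mean PC1/PC2 and displacement from each group's baseline day.

    Only study samples present in the PCA score table are used; the
    baseline is each group's earliest sampled day.
    """
    scores = pca.scores if hasattr(pca, "scores") else pca
    meta = sample_meta.loc[scores.index]
    study = meta["sample_type"] == "study"
    sc = scores.loc[study]
    meta = meta.loc[study]
    if sc.empty:
        raise ValueError("no study samples in the score table")
    pc2 = sc.iloc[:, 1] if sc.shape[1] > 1 else pd.Series(0.0, index=sc.index)
    df = pd.DataFrame(
        {"group": meta["group"], "day": meta["day"], "pc1": sc.iloc[:, 0], "pc2": pc2}
    )
    rows = []
    for g, gdf in df.groupby("group", sort=True):
        days = sorted(gdf["day"].unique())
        means = gdf.groupby("day")[["pc1", "pc2"]].mean()
        counts = gdf.groupby("day").size()
        if (counts < 1).any():
            raise ValueError(f"group {g} has an empty day stratum")
        base = means.loc[days[0]]
        for d in days:
            disp = float(np.hypot(*(means.loc[d] - base)))
            rows.append(
                {
                    "group": g,
                    "day": d,
                    "pc1": float(means.loc[d, "pc1"]),
                    "pc2": float(means.loc[d, "pc2"]),
                    "displacement": disp,
                }
            )
    return Trajectory(pd.DataFrame(rows))


# ------------------------------------------------------------ principal curve


@dataclass
class PrincipalCurve:
    vertices: np.ndarray  # ordered m × d polyline through the cloud
    arc_lengths: np.ndarray  # cumulative, 0 .. total_length
    total_length: float
    pca_mean: np.ndarray
    pca_components: np.ndarray  # d × n_features (projection into curve space)
    feature_names: pd.Index | None
    converged: bool
    n_iter: int
    final_sq_dist: float

    def to_reduced(self, X) -> np.ndarray:
        """Project feature-space rows into the curve's reduced space."""
        X = np.asarray(X, dtype=float)
        return (X - self.pca_mean) @ self.pca_components.T


def _local_linear(values: np.ndarray, lam: np.ndarray, span: float) -> np.ndarray:
    """Local degree-1 fit over a rank window of span·n points.

    A locally linear smoother is exact on linear data — including at the
    boundaries, where a plain moving average would pull the curve ends
    inward and collapse extreme samples onto the end vertices.
    """
    n = values.size
    k = max(3, int(np.ceil(span * n)))
    half = k // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x = lam[lo:hi] - lam[i]
        y = values[lo:hi]
        sx = x.sum()
        sxx = (x * x).sum()
        m = hi - lo
        det = m * sxx - sx * sx
        if det <= 1e-30:
            out[i] = y.mean()
        else:
            # intercept of the least-squares line at x = 0
            out[i] = (sxx * y.sum() - sx * (x * y).sum()) / det
    return out


def _project_to_polyline(points: np.ndarray, vertices: np.ndarray):
    """Arc-length parameter and orthogonal distance of each point.

    Vectorised over segments: for every point the nearest location on the
    polyline is found among all segments.
    """
    seg_a = vertices[:-1]  # s × d
    seg_v = vertices[1:] - vertices[:-1]
    seg_len2 = (seg_v**2).sum(axis=1)
    seg_len = np.sqrt(seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    nz = seg_len2 > 0
    lam = np.empty(points.shape[0])
    dist = np.empty(points.shape[0])
    diff = points[:, None, :] - seg_a[None, :, :]  # n × s × d
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("nsd,sd->ns", diff, seg_v) / seg_len2
    t[:, ~nz] = 0.0
    t = np.clip(t, 0.0, 1.0)
    proj = seg_a[None, :, :] + t[:, :, None] * seg_v[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    rows = np.arange(points.shape[0])
    lam = cum[best] + t[rows, best] * seg_len[best]
    dist = np.sqrt(d2[rows, best])
    return lam, dist


def fit_principal_curve(
    matrix,
    healthy_ids,
    n_pcs: int | None = None,
    variance_target: float = 0.85,
    span: float = 0.3,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> PrincipalCurve:
    """Hastie–Stuetzle principal curve through the biomarker matrix.

    The matrix (samples × selected biomarkers, already scaled) is reduced
    to its top principal components (smallest count explaining
    ``variance_target`` of the variance unless ``n_pcs`` is given).  The
    curve is initialised on the first PC segment and alternates
    projection, per-coordinate locally linear smoothing against the
    current arc-length parameter, and arc-length reparametrisation, until
    the total squared projection distance stabilises.  Orientation: the healthy
    samples' mean parameter is placed at the low (zero) end.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("principal curve needs at least three samples")
    if X.std(axis=0).max() == 0:
        raise ValueError("degenerate zero-variance input")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    full = fit_pca(X, n_components=max_rank)
    if n_pcs is None:
        cum = np.cumsum(full.explained_variance_ratio)
        n_pcs = int(np.searchsorted(cum, variance_target) + 1)
    n_pcs = int(min(max(n_pcs, 1), max_rank))
    Z = full.scores.to_numpy()[:, :n_pcs]

    lam = Z[:, 0].copy()
    prev_sq = np.inf
    converged = False
    vertices = None
    for it in range(1, max_iter + 1):
        order = np.argsort(lam, kind="stable")
        lam_sorted = lam[order]
        smoothed = np.column_stack(
            [_local_linear(Z[order, j], lam_sorted, span) for j in range(n_pcs)]
        )
        # drop consecutive duplicate vertices (zero-length segments)
        keep = np.ones(len(smoothed), dtype=bool)
        keep[1:] = (np.diff(smoothed, axis=0) ** 2).sum(axis=1) > 1e-300
        vertices = smoothed[keep]
        if vertices.shape[0] < 2:
            raise ValueError("curve collapsed to a point")
        lam, dist = _project_to_polyline(Z, vertices)
        sq = float((dist**2).sum())
        if prev_sq < np.inf and abs(prev_sq - sq) <= tol * max(prev_sq, 1e-12):
            converged = True
            break
        prev_sq = sq

    seg = np.sqrt((np.diff(vertices, axis=0) ** 2).sum(axis=1))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(arc[-1])
    if total == 0:
        raise ValueError("zero-length curve")

    # orient: healthy end at parameter 0
    if is_frame:
        healthy_mask = matrix.index.isin(pd.Index(healthy_ids))
    else:
        healthy_mask = np.zeros(X.shape[0], dtype=bool)
        healthy_mask[np.asarray(healthy_ids, dtype=int)] = True
    if not healthy_mask.any():
        raise ValueError("no healthy samples found in the matrix")
    if lam[healthy_mask].mean() > total / 2.0:
        vertices = vertices[::-1].copy()
        arc = total - arc[::-1]

    return PrincipalCurve(
        vertices=vertices,
        arc_lengths=arc,
        total_length=total,
        pca_mean=full.mean_,
        pca_components=full.loadings.to_numpy().T[:n_pcs],
        feature_names=matrix.columns if is_frame else None,
        converged=converged,
        n_iter=it,
        final_sq_dist=float((dist**2).sum()),
    )


# ------------------------------------------------------------ MDS


@dataclass
class MdsResult:
    samples: pd.DataFrame  # sample_id (index), mds, residual [+ group/animal/day]

    def group_day_summary(self) -> pd.DataFrame:
        if "group" not in self.samples.columns:
            raise ValueError("sample metadata not attached")
        g = self.samples.groupby(["group", "day"])["mds"]
        return g.agg(["mean", "std", "count"]).reset_index()


def compute_mds(curve: PrincipalCurve, matrix, sample_meta: pd.DataFrame | None = None) -> MdsResult:
    """Project samples onto the curve; MDS = arc-length position / length.

    ``matrix`` may be in the original feature space (columns matching the
    fit) or already in the curve's reduced space.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if curve.total_length <= 0:
        raise ValueError("zero-length curve")
    if X.shape[1] == curve.pca_components.shape[1]:
        Z = curve.to_reduced(X)
    elif X.shape[1] == curve.vertices.shape[1]:
        Z = X
    else:
        raise ValueError("samples are in neither the feature nor the reduced space")
    lam, dist = _project_to_polyline(Z, curve.vertices)
    mds = np.clip(lam / curve.total_length, 0.0, 1.0)
    idx = matrix.index if is_frame else pd.RangeIndex(X.shape[0])
    df = pd.DataFrame({"mds": mds, "residual": dist}, index=idx)
    if sample_meta is not None:
        df = df.join(sample_meta[["group", "animal_id", "day"]])
    return MdsResult(samples=df)


def mds_auc(result: MdsResult, days=None):
    """Per-animal trapezoidal MDS-vs-day area and pairwise group tests.

    Returns ``(auc_frame, tests_frame)``; ``days`` restricts the window
    (default: every sampled day).  Each animal needs at least two days.
    """
    df = result.samples
    if "animal_id" not in df.columns:
        raise ValueError("sample metadata not attached to the MDS result")
    if days is not None:
        df = df[df["day"].isin(list(days))]
    rows = []
    for (animal, group), adf in df.groupby(["animal_id", "group"]):
        adf = adf.sort_values("day")
        if adf.shape[0] < 2:
            raise ValueError(f"animal {animal} sampled on fewer than two days")
        auc = stats.trapezoid_auc(adf["mds"].to_numpy(), adf["day"].to_numpy())
        rows.append({"animal_id": animal, "group": group, "auc": auc})
    auc_df = pd.DataFrame(rows)
    groups = sorted(auc_df["group"].unique())
    tests = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            xa = auc_df.loc[auc_df["group"] == ga, "auc"].to_numpy()
            xb = auc_df.loc[auc_df["group"] == gb, "auc"].to_numpy()
            res = stats.mann_whitney(xa, xb)
            tests.append(
                {"group_a": ga, "group_b": gb, "U": res.statistic, "p": res.p_value}
            )
    return auc_df, pd.DataFrame(tests)
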