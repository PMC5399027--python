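"""PCA and OPLS-DA with cross-validated quality metrics.

PCA is a plain SVD of the column-centred matrix; its Q² uses row-fold
cross-validation with leave-one-variable-out reconstruction of held-out
rows, so that Q² is an honest predictive fraction rather than a copy of
R²X.

OPLS-DA follows the O-PLS decomposition: orthogonal components are
stripped (weights orthogonal to the y-predictive weight vector) before a
final one-component PLS fit, so orthogonal scores have exactly zero sample
correlation with the response.  With ``n_orth=0`` the model *is* the
one-component PLS1 solution.  VIP is computed over predictive plus
orthogonal components weighted by explained response sum of squares; since
orthogonal components explain none of y, the normalisation Σ VIP² = p
holds identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------- PCA


@dataclass
class PcaModel:
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # features × components, orthonormal
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray
    r2x: float  # cumulative over kept components
    q2: float | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def transform(self, X) -> np.ndarray:
        Xc = np.asarray(X, dtype=float) - self.mean_
        return Xc @ self.loadings.to_numpy()


def fit_pca(matrix, n_components: int) -> PcaModel:
    """Principal component analysis of a samples × features matrix."""
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least two samples")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc**2).sum())
    if total_var == 0:
        raise ValueError("degenerate all-constant matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    evr = (s**2) / total_var
    V = Vt[:n_components].T
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_components):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    T = Xc @ V
    idx = matrix.index if is_frame else pd.RangeIndex(n)
    cols = matrix.columns if is_frame else pd.RangeIndex(p)
    comp = [f"PC{k + 1}" for k in range(n_components)]
    return PcaModel(
        scores=pd.DataFrame(T, index=idx, columns=comp),
        loadings=pd.DataFrame(V, index=cols, columns=comp),
        explained_variance_ratio=evr[:n_components].copy(),
        mean_=mean,
        r2x=float(evr[:n_components].sum()),
    )


def pca_q2(matrix, n_components: int, k_folds: int = 7, seed: int = 0) -> float:
    """Cross-validated Q² of a PCA model.

    Rows are held out fold-wise; each held-out cell is predicted from the
    row's *other* variables via the training loadings (rank-one downdate of
    the normal equations), giving PRESS that can genuinely exceed chance.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    k_folds = min(k_folds, n)
    if k_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    fold = rng.permutation(n) % k_folds
    press = 0.0
    ss = 0.0
    for f in range(k_folds):
        train, test = X[fold != f], X[fold == f]
        if train.shape[0] <= n_components:
            raise ValueError("fold too small for the requested rank")
        mean = train.mean(axis=0)
        Xc = train - mean
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        P = Vt[:n_components].T  # p × k, orthonormal
        Tc = test - mean
        B = Tc @ P  # rows' full-score estimates, m × k
        norm2 = (P**2).sum(axis=1)  # |P_j|² per variable
        # score estimate excluding variable j: Sherman–Morrison on (I − P_j P_jᵀ)
        for j in range(X.shape[1]):
            pj = P[j]
            denom = 1.0 - norm2[j]
            bj = B - np.outer(Tc[:, j], pj)
            if abs(denom) < 1e-12:
                t = bj
            else:
                t = bj + np.outer(bj @ pj, pj) / denom
            pred = t @ pj
            press += float(((Tc[:, j] - pred) ** 2).sum())
        ss += float((Tc**2).sum())
    return 1.0 - press / ss


# ---------------------------------------------------------------- OPLS-DA


@dataclass
class OplsModel:
    """O-PLS discriminant model: one predictive + ``n_orth`` orthogonal components."""

    w_pred: np.ndarray  # predictive weights (unit norm)
    p_pred: np.ndarray  # predictive loadings
    t_pred: np.ndarray  # predictive scores
    c_pred: float  # y loading
    W_orth: np.ndarray  # p × n_orth
    P_orth: np.ndarray
    T_orth: np.ndarray  # n × n_orth
    mean_: np.ndarray
    y_mean: float
    classes_: tuple
    positive_class: object
    r2x: float
    r2y: float
    q2: float | None = None
    feature_names: pd.Index | None = None
    ssy_explained: float = 0.0
    ssy_total: float = 0.0
    vip: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_orth(self) -> int:
        return self.T_orth.shape[1]

    def encode_y(self, y_labels) -> np.ndarray:
        y = np.asarray(y_labels)
        out = np.where(y == self.positive_class, 1.0, -1.0)
        return out

    def transform(self, X):
        """Return (t_pred, T_orth) for new rows after orthogonal stripping."""
        Xc = np.asarray(X, dtype=float) - self.mean_
        T_o = np.zeros((Xc.shape[0], self.n_orth))
        for a in range(self.n_orth):
            t_o = Xc @ self.W_orth[:, a]
            T_o[:, a] = t_o
            Xc = Xc - np.outer(t_o, self.P_orth[:, a])
        return Xc @ self.w_pred, T_o

    def predict_y(self, X) -> np.ndarray:
        t, _ = self.transform(X)
        return t * self.c_pred + self.y_mean


def _encode_labels(y_labels, positive_class=None):
    y = np.asarray(y_labels)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA needs exactly two classes, got {classes}")
    if positive_class is None:
        positive_class = classes[0]  # first label lexicographically is positive
    if positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not among {classes}")
    yc = np.where(y == positive_class, 1.0, -1.0)
    return yc, tuple(classes), positive_class


def fit_oplsda(matrix, y_labels, n_orth: int = 1, positive_class=None) -> OplsModel:
    """Fit an OPLS-DA model with ``n_orth`` orthogonal components.

    The matrix is expected already scaled (e.g. Pareto); it is centred
    internally.  Scores are sign-fixed so the positive class has positive
    mean predictive score.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    y_num, classes, positive_class = _encode_labels(y_labels, positive_class)
    if X.shape[0] != y_num.size:
        raise ValueError("matrix rows and labels disagree")
    mean = X.mean(axis=0)
    Xc = X - mean
    ssx_total = float((Xc**2).sum())
    if ssx_total == 0:
        raise ValueError("degenerate all-constant matrix")
    y_mean = float(y_num.mean())
    yc = y_num - y_mean
    ssy_total = float((yc**2).sum())

    Xres = Xc.copy()
    W_o, P_o, T_o = [], [], []
    ssx_orth = 0.0
    for _ in range(n_orth):
        w = Xres.T @ yc
        w_norm = np.linalg.norm(w)
        if w_norm == 0:
            break
        w = w / w_norm
        t = Xres @ w
        p = Xres.T @ t / float(t @ t)
        w_orth = p - float(w @ p) * w
        norm_o = np.linalg.norm(w_orth)
        if norm_o < 1e-10:
            break  # no y-orthogonal structure left
        w_orth = w_orth / norm_o
        t_orth = Xres @ w_orth
        p_orth = Xres.T @ t_orth / float(t_orth @ t_orth)
        Xres = Xres - np.outer(t_orth, p_orth)
        W_o.append(w_orth)
        P_o.append(p_orth)
        T_o.append(t_orth)
        ssx_orth += float(t_orth @ t_orth) * float(p_orth @ p_orth)

    w = Xres.T @ yc
    w_norm = np.linalg.norm(w)
    if w_norm == 0:
        raise ValueError("response carries no covariance with the matrix")
    w = w / w_norm
    t = Xres @ w
    tt = float(t @ t)
    p = Xres.T @ t / tt
    c = float(yc @ t) / tt
    # sign fix: positive class mean score positive
    if t[y_num > 0].mean() < 0:
        w, t, p, c = -w, -t, -p, -c

    ssy_expl = c**2 * tt
    r2y = ssy_expl / ssy_total
    r2x = (tt * float(p @ p) + ssx_orth) / ssx_total
    k = len(W_o)
    model = OplsModel(
        w_pred=w,
        p_pred=p,
        t_pred=t,
        c_pred=c,
        W_orth=np.column_stack(W_o) if k else np.zeros((X.shape[1], 0)),
        P_orth=np.column_stack(P_o) if k else np.zeros((X.shape[1], 0)),
        T_orth=np.column_stack(T_o) if k else np.zeros((X.shape[0], 0)),
        mean_=mean,
        y_mean=y_mean,
        classes_=classes,
        positive_class=positive_class,
        r2x=float(r2x),
        r2y=float(r2y),
        feature_names=matrix.columns if is_frame else None,
        ssy_explained=float(ssy_expl),
        ssy_total=ssy_total,
    )
    model.vip = compute_vip(model)
    return model


def compute_vip(model: OplsModel) -> np.ndarray:
    """Variable importance in the projection.

    VIP_j = sqrt(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a) over the
    predictive plus orthogonal components; orthogonal components have
    SSY_a = 0 so Σ_j VIP_j² = p exactly.
    """
    if model.ssy_explained <= 0:
        raise ValueError("model explains no response variation")
    p = model.w_pred.size
    num = model.ssy_explained * (model.w_pred / np.linalg.norm(model.w_pred)) ** 2
    # orthogonal components contribute SSY_a = 0 terms
    return np.sqrt(p * num / model.ssy_explained)


def s_plot(model: OplsModel, matrix):
    """Per-feature covariance and correlation with the predictive score.

    Returns a DataFrame with columns ``p`` (covariance) and ``pcorr``
    (correlation).  Raises on a constant feature column.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_frame else np.asarray(matrix, dtype=float)
    t = model.t_pred
    if X.shape[0] != t.size:
        raise ValueError("matrix rows and model scores disagree")
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    n = t.size
    cov = Xc.T @ tc / (n - 1)
    sx = X.std(axis=0, ddof=1)
    st = t.std(ddof=1)
    if np.any(sx == 0):
        cols = matrix.columns[sx == 0].tolist() if is_frame else np.flatnonzero(sx == 0)
        raise ValueError(f"constant feature columns: {list(cols)[:5]}")
    pcorr = cov / (sx * st)
    idx = matrix.columns if is_frame else pd.RangeIndex(X.shape[1])
    return pd.DataFrame({"p": cov, "pcorr": pcorr}, index=idx)


# ---------------------------------------------------------------- CV


def _stratified_folds(y_num: np.ndarray, k_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (both classes per fold)."""
    rng = np.random.default_rng(seed)
    fold = np.empty(y_num.size, dtype=int)
    for cls in np.unique(y_num):
        idx = np.flatnonzero(y_num == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k_folds
    return fold


def cross_validate_oplsda(
    matrix, y_labels, n_orth: int = 1, k_folds: int = 7, seed: int = 0,
    positive_class=None,
):
    """K-fold Q² (and full-data R²Y) for an OPLS-DA model spec.

    Q² = 1 − PRESS/SS over held-out class predictions, with folds
    stratified by class.  Deterministic given ``seed``.
    """
    X = (
        matrix.to_numpy(dtype=float)
        if isinstance(matrix, pd.DataFrame)
        else np.asarray(matrix, dtype=float)
    )
    y_num, classes, positive_class = _encode_labels(y_labels, positive_class)
    n = y_num.size
    k_folds = min(k_folds, int(np.bincount((y_num > 0).astype(int)).min()))
    if k_folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    fold = _stratified_folds(y_num, k_folds, seed)
    press = 0.0
    for f in range(k_folds):
        tr, te = fold != f, fold == f
        if np.unique(y_num[tr]).size < 2:
            raise ValueError("a training fold lost one class")
        sub = fit_oplsda(X[tr], y_num[tr], n_orth=n_orth, positive_class=1.0)
        pred = sub.predict_y(X[te])
        press += float(((y_num[te] - pred) ** 2).sum())
    ss = float(((y_num - y_num.mean()) ** 2).sum())
    q2 = 1.0 - press / ss
    full = fit_oplsda(X, y_num, n_orth=n_orth, positive_class=1.0)
    return q2, full.r2y


def select_n_orth(
    matrix, y_labels, max_orth: int = 3, k_folds: int = 7, seed: int = 0,
    min_improvement: float = 0.01,
) -> int:
    """Grow orthogonal components while cross-validated Q² improves enough."""
    best_k, best_q2 = 0, cross_validate_oplsda(matrix, y_labels, 0, k_folds, seed)[0]
    for k in range(1, max_orth + 1):
        q2 = cross_validate_oplsda(matrix, y_labels, k, k_folds, seed)[0]
        if q2 > best_q2 + min_improvement:
            best_k, best_q2 = k, q2
        else:
            break
    return best_k
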