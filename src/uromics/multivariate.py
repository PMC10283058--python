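"""Unsupervised and supervised projection models.

PCA (scikit-learn backed) and an orthogonal projections to latent
structures discriminant analysis (OPLS-DA) written from the published
O-PLS algorithm: orthogonal components — variation in X uncorrelated
with the class code — are stripped first, then a single predictive PLS
component is fitted on the deflated matrix.  With zero orthogonal
components the model reduces exactly to single-component PLS1.

Class coding is -1/+1; unit-variance scaling is on by default.  Model
quality is summarized by R2X per component, R2Y and a cross-validated Q2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PcaModel", "OplsdaModel", "fit_pca", "fit_oplsda", "oplsda_q2"]


@dataclass
class PcaModel:
    scores: np.ndarray
    loadings: np.ndarray               # components x features, orthonormal rows
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None
    feature_ids: list

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, dtype=float) - self.mean
        if self.scale is not None:
            Xc = Xc / self.scale
        return Xc @ self.loadings.T


def fit_pca(matrix: pd.DataFrame | np.ndarray, n_components: int = 2,
            scale: bool = False) -> PcaModel:
    """Principal component analysis of a samples x features matrix.

    The matrix is centred internally; with ``scale=True`` columns are
    also divided by their SD.  Constant matrices (zero total variance)
    are rejected.
    """
    feature_ids = (list(matrix.columns) if isinstance(matrix, pd.DataFrame)
                   else [str(i) for i in range(np.asarray(matrix).shape[1])])
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds min(samples-1, features)")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("matrix has zero variance")
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xc)
    return PcaModel(scores=scores, loadings=pca.components_,
                    explained_variance_ratio=pca.explained_variance_ratio_,
                    mean=mean, scale=sd, feature_ids=feature_ids)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsdaModel:
    predictive_weights: np.ndarray      # w, unit norm
    predictive_loadings: np.ndarray     # p
    predictive_scores: np.ndarray       # t
    q: float                            # regression of y on t
    orthogonal_weights: np.ndarray      # k x features
    orthogonal_loadings: np.ndarray
    orthogonal_scores: np.ndarray       # n x k
    r2x_per_component: np.ndarray       # predictive first, then orthogonal
    r2y: float
    q2: float | None
    class_labels: tuple
    y_code: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None
    y_mean: float
    feature_ids: list = field(default_factory=list)

    def _preprocess(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, dtype=float) - self.mean
        if self.scale is not None:
            Xc = Xc / self.scale
        return Xc

    def transform(self, X: np.ndarray):
        """Return (predictive score, orthogonal scores) for new samples."""
        Xc = self._preprocess(np.atleast_2d(X))
        t_orth = np.zeros((Xc.shape[0], self.orthogonal_weights.shape[0]))
        for k in range(self.orthogonal_weights.shape[0]):
            t_o = Xc @ self.orthogonal_weights[k]
            Xc = Xc - np.outer(t_o, self.orthogonal_loadings[k])
            t_orth[:, k] = t_o
        return Xc @ self.predictive_weights, t_orth

    def predict_code(self, X: np.ndarray) -> np.ndarray:
        """Continuous prediction of the -1/+1 class code."""
        t, _ = self.transform(X)
        return self.y_mean + t * self.q


def _encode_labels(labels) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = tuple(sorted(pd.unique(labels)))
    if len(classes) != 2:
        raise ValueError("OPLS-DA requires exactly two classes")
    y = np.where(labels == classes[1], 1.0, -1.0)
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has < 2 samples")
    return y, classes


def fit_oplsda(matrix: pd.DataFrame | np.ndarray, labels,
               n_orthogonal: int = 1, scale: bool = True,
               compute_q2: bool = True, folds: int = 7,
               seed: int = 0) -> OplsdaModel:
    """Fit OPLS-DA with one predictive and ``n_orthogonal`` components.

    Each orthogonal component is, per the O-PLS algorithm, the dominant
    direction of X-variation whose weight vector is orthogonalized
    against the y-predictive weight; its scores are exactly uncorrelated
    with the class code by construction.  Deflation preserves the total
    sum of squares: ssX = sum of component SS + residual SS.
    """
    feature_ids = (list(matrix.columns) if isinstance(matrix, pd.DataFrame)
                   else [])
    X = np.asarray(matrix, dtype=float)
    y, classes = _encode_labels(labels)

    mean = X.mean(axis=0)
    Xc = X - mean
    sd = None
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    y_mean = float(y.mean())
    yc = y - y_mean

    rank = np.linalg.matrix_rank(Xc)
    if n_orthogonal >= rank:
        raise ValueError(
            f"n_orthogonal={n_orthogonal} >= rank {rank}; "
            f"at most {rank - 1} orthogonal components are extractable")

    ss_total = float(np.sum(Xc ** 2))
    E = Xc.copy()
    W_o, P_o, T_o, ss_comp = [], [], [], []

    for _ in range(n_orthogonal):
        w = E.T @ yc
        w /= np.linalg.norm(w)
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w          # orthogonalize against predictive weight
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            break
        w_o /= nrm
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        W_o.append(w_o); P_o.append(p_o); T_o.append(t_o)
        ss_comp.append(float(t_o @ t_o * (p_o @ p_o)))

    w = E.T @ yc
    w /= np.linalg.norm(w)
    t = E @ w
    p = E.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    ss_pred = float((t @ t) * (p @ p))

    y_hat = y_mean + t * q
    r2y = 1.0 - float(np.sum((y - y_hat) ** 2) / np.sum(yc ** 2))

    r2x = np.array([ss_pred] + ss_comp) / ss_total

    q2 = None
    model = OplsdaModel(
        predictive_weights=w, predictive_loadings=p, predictive_scores=t,
        q=q,
        orthogonal_weights=np.array(W_o).reshape(len(W_o), X.shape[1]),
        orthogonal_loadings=np.array(P_o).reshape(len(P_o), X.shape[1]),
        orthogonal_scores=(np.column_stack(T_o) if T_o
                           else np.zeros((X.shape[0], 0))),
        r2x_per_component=r2x, r2y=r2y, q2=None,
        class_labels=classes, y_code=y, mean=mean, scale=sd,
        y_mean=y_mean, feature_ids=feature_ids,
    )
    if compute_q2:
        model.q2 = oplsda_q2(X, labels, n_orthogonal=n_orthogonal,
                             folds=folds, scale=scale, seed=seed)
    return model


def oplsda_q2(matrix, labels, n_orthogonal: int = 1, folds: int = 7,
              scale: bool = True, seed: int = 0) -> float:
    """Cross-validated Q2 = 1 - PRESS/TSS over held-out class codes.

    Folds are stratified by class so every training fold contains both
    classes; single-class input is rejected (TSS undefined).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(matrix, dtype=float)
    y, classes = _encode_labels(labels)
    labels = np.asarray(labels)

    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    for c in classes:
        idx = np.where(labels == c)[0]
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % folds

    press = 0.0
    tss = float(np.sum((y - y.mean()) ** 2))
    for k in range(folds):
        test = fold_of == k
        if test.sum() == 0:
            continue
        train = ~test
        if len(np.unique(labels[train])) < 2:
            raise ValueError("a CV fold lost one class entirely")
        m = fit_oplsda(X[train], labels[train], n_orthogonal=n_orthogonal,
                       scale=scale, compute_q2=False)
        y_hat = m.predict_code(X[test])
        press += float(np.sum((y[test] - y_hat) ** 2))
    return 1.0 - press / tss
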