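"""Seven-algorithm pairwise-prediction harness.

Stratified 2:1 discovery/validation splitting, hyperparameter selection
by stratified 10-fold cross-validation on the discovery set only, the
full evaluation-metric suite (confusion matrix, accuracy, precision,
sensitivity, specificity, F-measure, Cohen's kappa, ROC/AUC), and the
single- versus multi-omics comparison in which the metabolite and
peptide blocks are concatenated after per-block standardization.

The seven algorithms are support vector machine (SVM), decision tree
(DT), Gaussian naive Bayes (NB), logistic regression (Logi), linear
discriminant analysis (LDA), k-nearest neighbours (KNN) and L1-penalized
logistic regression (LASSO).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ALGORITHMS",
    "SplitPlan",
    "EvaluationReport",
    "split_discovery_validation",
    "train_pairwise",
    "evaluate",
    "compare_single_vs_multiomics",
]

#: hyperparameter grids per algorithm (fixed and logged in run outputs);
#: only odd k for KNN so majority votes cannot tie
_GRIDS = {
    "SVM": [{"clf__kernel": ["linear"], "clf__C": [0.1, 1.0, 10.0]},
            {"clf__kernel": ["rbf"], "clf__C": [1.0, 10.0],
             "clf__gamma": ["scale", 0.1]}],
    "DT": {"clf__max_depth": [3, 5, None]},
    "NB": {},
    "Logi": {"clf__C": [0.1, 1.0, 10.0]},
    "LDA": {},
    "KNN": {"clf__n_neighbors": [3, 5, 7, 9]},
    "LASSO": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
}

ALGORITHMS = tuple(_GRIDS)


def _estimator(name: str, seed: int):
    if name == "SVM":
        return SVC(random_state=seed)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "NB":
        return GaussianNB()
    if name == "Logi":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "LASSO":
        return LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                  max_iter=2000, random_state=seed)
    raise ValueError(f"unknown algorithm {name!r}; choose from {ALGORITHMS}")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    discovery_ids: list
    validation_ids: list
    ratio: tuple
    seed: int

    def to_dict(self) -> dict:
        return {"discovery_ids": list(self.discovery_ids),
                "validation_ids": list(self.validation_ids),
                "ratio": list(self.ratio), "seed": self.seed}


def split_discovery_validation(sample_ids: Sequence, labels: Sequence,
                               ratio: tuple = (2, 1),
                               seed: int = 0) -> SplitPlan:
    """Stratified random discovery/validation split at ``ratio`` (2:1).

    Per class, round(n / (d+v) * v) samples go to validation, which keeps
    each class's discovery:validation counts within +-1 of the target.
    Classes with fewer than 3 samples are rejected by name.
    """
    sample_ids = np.asarray(sample_ids)
    labels = np.asarray(labels)
    if sample_ids.shape != labels.shape:
        raise ValueError("sample_ids and labels must align")
    d, v = ratio
    rng = np.random.default_rng(seed)
    disc, val = [], []
    for c in pd.unique(labels):
        idx = np.where(labels == c)[0]
        if idx.size < 3:
            raise ValueError(f"class {c!r} has {idx.size} samples (< 3)")
        rng.shuffle(idx)
        n_val = int(round(idx.size * v / (d + v)))
        n_val = min(max(n_val, 1), idx.size - 1)
        val.extend(sample_ids[idx[:n_val]])
        disc.extend(sample_ids[idx[n_val:]])
    return SplitPlan(discovery_ids=disc, validation_ids=val,
                     ratio=tuple(ratio), seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class PairwiseScorer:
    """A fitted binary scorer producing probability-like scores in [0,1]."""

    def __init__(self, pipeline, classes, majority_fallback=None,
                 best_params=None, cv_accuracy=None):
        self.pipeline = pipeline
        self.classes = classes
        self.majority_fallback = majority_fallback
        self.best_params = best_params or {}
        self.cv_accuracy = cv_accuracy

    def score_samples(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.majority_fallback is not None:
            p = 1.0 if self.majority_fallback == self.classes[1] else 0.0
            return np.full(X.shape[0], p)
        clf = self.pipeline
        if hasattr(clf, "predict_proba"):
            proba = clf.predict_proba(X)
            pos = list(clf.classes_).index(self.classes[1])
            return proba[:, pos]
        d = clf.decision_function(X)
        return expit(d)

    def predict(self, X) -> np.ndarray:
        scores = self.score_samples(X)
        return np.where(scores >= 0.5, self.classes[1], self.classes[0])


def train_pairwise(algorithm: str, matrix, labels, folds: int = 10,
                   seed: int = 0) -> PairwiseScorer:
    """Fit one algorithm with stratified CV hyperparameter selection.

    Only the data passed here (the discovery set) is ever seen by the
    cross-validation; scores for new samples come from the model's native
    probability where defined, otherwise a logistic link on the decision
    value.  Constant-feature-only input falls back to a flagged
    majority-class scorer.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) != 2:
        raise ValueError("train_pairwise requires binary labels")
    counts = {c: int((y == c).sum()) for c in classes}
    folds = min(folds, min(counts.values()))
    if folds < 2:
        raise ValueError("need >= 2 samples per class for CV")

    if np.all(X.std(axis=0) == 0):
        major = classes[int(counts[classes[1]] >= counts[classes[0]])]
        return PairwiseScorer(None, classes, majority_fallback=major)

    pipe = Pipeline([("scale", StandardScaler()),
                     ("clf", _estimator(algorithm, seed))])
    grid = _GRIDS[algorithm]
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    if grid:
        search = GridSearchCV(pipe, grid, cv=cv, scoring="accuracy",
                              n_jobs=1, refit=True)
        search.fit(X, y)
        return PairwiseScorer(search.best_estimator_, classes,
                              best_params=search.best_params_,
                              cv_accuracy=float(search.best_score_))
    from sklearn.model_selection import cross_val_score
    acc = float(np.mean(cross_val_score(pipe, X, y, cv=cv, scoring="accuracy")))
    pipe.fit(X, y)
    return PairwiseScorer(pipe, classes, cv_accuracy=acc)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    confusion: np.ndarray               # rows true [neg, pos], cols predicted
    accuracy: float
    precision: float
    recall: float                       # sensitivity of the positive class
    specificity: float
    f_measure: float
    kappa: float
    auc: float
    roc_points: np.ndarray | None = None
    predicted_ratio: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity,
            "f_measure": self.f_measure, "kappa": self.kappa,
            "auc": self.auc, "predicted_ratio": self.predicted_ratio,
            "notes": self.notes,
        }


def evaluate(truth, predicted=None, scores=None, positive=None,
             cutoff: float = 0.5) -> EvaluationReport:
    """Binary evaluation report from labels and/or continuous scores.

    Metrics follow their standard definitions; kappa is (po - pe)/(1 - pe)
    with chance agreement from the marginals; AUC is the Mann-Whitney
    rank statistic (ties counted 1/2) and needs both classes and scores.
    With only scores given, labels are thresholded at ``cutoff``.
    """
    truth = np.asarray(truth)
    classes = sorted(pd.unique(truth))
    if positive is None:
        positive = classes[-1]
    pos = truth == positive
    if predicted is None:
        if scores is None:
            raise ValueError("need predicted labels or scores")
        predicted_pos = np.asarray(scores, dtype=float) >= cutoff
    else:
        predicted = np.asarray(predicted)
        if predicted.shape != truth.shape:
            raise ValueError("truth and prediction lengths differ")
        predicted_pos = predicted == positive

    tp = int(np.sum(pos & predicted_pos))
    fn = int(np.sum(pos & ~predicted_pos))
    fp = int(np.sum(~pos & predicted_pos))
    tn = int(np.sum(~pos & ~predicted_pos))
    n = tp + fn + fp + tn

    notes: list[str] = []
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    f_measure = (2 * precision * recall / (precision + recall)
                 if precision + recall else 0.0)

    po = accuracy
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = (po - pe) / (1 - pe) if pe != 1 else 0.0

    auc = float("nan")
    roc_points = None
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if pos.all() or (~pos).all():
            notes.append("one true class absent; AUC undefined")
        else:
            auc = float(roc_auc_score(pos.astype(int), scores))
            fpr, tpr, thr = roc_curve(pos.astype(int), scores)
            roc_points = np.column_stack([fpr, tpr, thr])
    elif pos.all() or (~pos).all():
        notes.append("one true class absent; class-conditional metrics undefined")

    negative = ([c for c in classes if c != positive][0]
                if len(classes) > 1 else f"not_{positive}")
    pred_labels = np.array([positive if p else negative
                            for p in predicted_pos], dtype=object)
    ratio = {}
    for c in classes:
        sel = truth == c
        ratio[str(c)] = {str(p): float(np.mean(pred_labels[sel] == p))
                         for p in pd.unique(pred_labels)}

    return EvaluationReport(
        confusion=np.array([[tn, fp], [fn, tp]]), accuracy=accuracy,
        precision=precision, recall=recall, specificity=specificity,
        f_measure=f_measure, kappa=kappa, auc=auc,
        roc_points=roc_points, predicted_ratio=ratio, notes=notes,
    )


# ---------------------------------------------------------------------------
# single- vs multi-omics comparison
# ---------------------------------------------------------------------------

def combine_blocks(met: pd.DataFrame, pep: pd.DataFrame) -> pd.DataFrame:
    """Concatenate two modality blocks after per-feature z-scoring within
    each block, so neither intensity scale dominates."""
    if not met.index.equals(pep.index):
        raise ValueError("modality blocks must share sample ids")

    def z(df):
        sd = df.std(axis=0, ddof=1).replace(0, 1.0)
        return (df - df.mean(axis=0)) / sd

    return pd.concat([z(met), z(pep)], axis=1)


def compare_single_vs_multiomics(met: pd.DataFrame, pep: pd.DataFrame,
                                 labels: pd.Series,
                                 algorithms: Sequence[str] = ALGORITHMS,
                                 folds: int = 10, ratio: tuple = (2, 1),
                                 seed: int = 0) -> pd.DataFrame:
    """Validation metrics per algorithm for metabolite-only, peptide-only
    and combined feature sources, plus the across-algorithm mean accuracy
    per source (rows ``algorithm == 'MEAN'``)."""
    if not met.index.equals(pep.index):
        offenders = met.index.symmetric_difference(pep.index).tolist()
        raise ValueError(f"sample id mismatch between modalities: {offenders[:5]}")
    labels = labels.reindex(met.index)
    plan = split_discovery_validation(met.index.to_numpy(),
                                      labels.to_numpy(), ratio=ratio,
                                      seed=seed)
    sources = {"met": met, "pep": pep, "combined": pd.concat([met, pep], axis=1)}
    rows = []
    for src_name, frame in sources.items():
        X_d = frame.loc[plan.discovery_ids]
        X_v = frame.loc[plan.validation_ids]
        if src_name == "combined":
            # per-block standardization fitted on discovery rows only
            stats_ = {}
            blocks = []
            for blk in (met, pep):
                mu = blk.loc[plan.discovery_ids].mean(axis=0)
                sd = blk.loc[plan.discovery_ids].std(axis=0, ddof=1).replace(0, 1.0)
                stats_[id(blk)] = (mu, sd)
                blocks.append(((blk - mu) / sd))
            both = pd.concat(blocks, axis=1)
            X_d, X_v = both.loc[plan.discovery_ids], both.loc[plan.validation_ids]
        y_d = labels.loc[plan.discovery_ids].to_numpy()
        y_v = labels.loc[plan.validation_ids].to_numpy()
        for alg in algorithms:
            scorer = train_pairwise(alg, X_d, y_d, folds=folds, seed=seed)
            rep = evaluate(y_v, predicted=scorer.predict(X_v),
                           scores=scorer.score_samples(X_v),
                           positive=scorer.classes[1])
            rows.append({"algorithm": alg, "source": src_name,
                         "accuracy": rep.accuracy, "precision": rep.precision,
                         "recall": rep.recall, "specificity": rep.specificity,
                         "f_measure": rep.f_measure, "kappa": rep.kappa,
                         "auc": rep.auc})
    table = pd.DataFrame(rows)
    means = (table.groupby("source", sort=False)["accuracy"].mean()
             .reset_index().assign(algorithm="MEAN"))
    return pd.concat([table, means], ignore_index=True)
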