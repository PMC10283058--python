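"""Three-step diagnostic cascade.

Layered binary L1-penalized logistic scorers routing each sample through
three ordered decisions: layer 1 separates healthy controls from all
patients; layer 2 separates uncomplicated type-2 diabetes from kidney
disease (grey-zone, early and overt DKD); layer 3 separates early DKD
from the remaining kidney-disease classes.  A sample stops at the first
layer that scores it on the negative side of that layer's cutoff, giving
a four-way terminal partition {HC, T2DM, EARLY_DKD, DKD_OTHER}; the
grey-zone report additionally measures how often grey-zone samples are
routed past layer 2 (i.e. recognized as kidney disease rather than plain
diabetes).

Each layer is a sparse linear model on raw feature values (panel,
coefficients, intercept) with a score cutoff, serializable to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CascadeLayer",
    "CascadeModel",
    "PredictionTrace",
    "select_panel_lasso",
    "choose_cutoff",
    "fit_cascade",
    "predict_cascade",
    "grey_zone_report",
]

TERMINAL_CLASSES = ("HC", "T2DM", "EARLY_DKD", "DKD_OTHER")


# ---------------------------------------------------------------------------
# LASSO panel selection
# ---------------------------------------------------------------------------

def select_panel_lasso(matrix: pd.DataFrame, labels, folds: int = 10,
                       lambda_rule: str = "1se", n_lambdas: int = 25,
                       seed: int = 0):
    """L1-penalized logistic panel over a regularization path.

    Features are standardized internally for the fit; the returned
    coefficients and intercept are folded back to the raw feature scale,
    so scoring new samples needs no scaler.  The penalty is chosen by
    stratified K-fold CV deviance: ``"min"`` takes the best mean
    deviance, ``"1se"`` (default) the sparsest model within one standard
    error of it.  If the selected penalty zeroes every coefficient the
    call is rejected, reporting the strongest penalty that still yields a
    nonempty panel.

    Returns ``(panel, coefficients, intercept, info)``.
    """
    if lambda_rule not in ("min", "1se", "nonempty_max"):
        raise ValueError("lambda_rule must be 'min', '1se' or 'nonempty_max'")
    X = matrix.to_numpy(dtype=float)
    y_raw = np.asarray(labels)
    classes = sorted(pd.unique(y_raw))
    if len(classes) != 2:
        raise ValueError("binary labels required")
    y = (y_raw == classes[1]).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    folds = min(folds, n_pos, n_neg)
    if folds < 2:
        raise ValueError("need >= 2 samples per class")

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    # path from the smallest penalty killing all coefficients downward;
    # floor ratio follows the glmnet convention (0.01 when n < p)
    c_max = np.abs(Z.T @ (y - y.mean())).max() / len(y)
    lam_max = 4.0 * c_max               # safety margin above the kill point
    min_ratio = 0.01 if len(y) < X.shape[1] else 1e-4
    lams = np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)
    Cs = 1.0 / (lams * len(y))

    if lambda_rule == "nonempty_max":
        # no CV: strongest penalty whose full-data refit keeps >= 1 feature
        # (robustness fallback when CV prefers the intercept-only model)
        for i, C in enumerate(Cs):
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                     max_iter=2000, random_state=seed)
            clf.fit(Z, y)
            if np.any(clf.coef_):
                return _fold_back(matrix, clf, mu, sd, {
                    "lambda": float(lams[i]), "rule": lambda_rule,
                    "classes": [str(c) for c in classes],
                    "cv_deviance": float("nan"), "folds": folds})
        raise ValueError("no penalty on the path yields a nonempty panel")

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((len(Cs), folds))
    for f, (tr, te) in enumerate(cv.split(Z, y)):
        for i, C in enumerate(Cs):
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                     max_iter=2000, random_state=seed)
            clf.fit(Z[tr], y[tr])
            p = np.clip(clf.predict_proba(Z[te])[:, 1], 1e-12, 1 - 1e-12)
            dev[i, f] = -2.0 * float(np.mean(y[te] * np.log(p)
                                             + (1 - y[te]) * np.log(1 - p)))
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(mean_dev))
    if lambda_rule == "min":
        i_sel = i_min
    else:
        # sparsest (largest lambda = smallest index) within 1 SE of the best
        ok = mean_dev <= mean_dev[i_min] + se_dev[i_min]
        i_sel = int(np.flatnonzero(ok)[0])

    clf = LogisticRegression(l1_ratio=1.0, C=Cs[i_sel], solver="liblinear",
                             max_iter=2000, random_state=seed)
    clf.fit(Z, y)
    coef_z = clf.coef_.ravel()
    nz = np.flatnonzero(coef_z)
    if nz.size == 0:
        # report the largest lambda on the path with a nonempty refit
        fallback = None
        for i in range(len(Cs)):
            c2 = LogisticRegression(l1_ratio=1.0, C=Cs[i], solver="liblinear",
                                    max_iter=2000, random_state=seed).fit(Z, y)
            if np.any(c2.coef_):
                fallback = lams[i]
                break
        raise ValueError(
            "selected penalty gives an empty panel; largest lambda with a "
            f"nonempty panel on this path: {fallback}")

    return _fold_back(matrix, clf, mu, sd, {
        "lambda": float(lams[i_sel]), "rule": lambda_rule,
        "classes": [str(c) for c in classes],
        "cv_deviance": float(mean_dev[i_sel]), "folds": folds,
    })


def _fold_back(matrix: pd.DataFrame, clf, mu, sd, info):
    """Express a standardized-scale logistic fit on the raw feature scale."""
    coef_z = clf.coef_.ravel()
    nz = np.flatnonzero(coef_z)
    panel = [matrix.columns[j] for j in nz]
    coef_raw = coef_z[nz] / sd[nz]
    intercept = float(clf.intercept_[0] - np.sum(coef_z[nz] * mu[nz] / sd[nz]))
    return panel, coef_raw, intercept, info


def choose_cutoff(scores, labels, method: str = "youden"):
    """Score cutoff for calling the positive class (score >= cutoff).

    ``"youden"`` scans the observed scores as candidate thresholds and
    returns the smallest one maximizing sensitivity + specificity - 1;
    when every threshold is uninformative (J = 0 throughout) the median
    score is returned, flagged.  ``"fixed"`` returns 0.5.
    Returns ``(cutoff, note)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if method == "fixed":
        return 0.5, ""
    if method != "youden":
        raise ValueError("method must be 'youden' or 'fixed'")
    if labels.all() or (~labels).all():
        raise ValueError("both classes required to choose a cutoff")
    if labels.sum() == 1:
        return float(scores[labels][0]), "single positive sample; low-n cutoff"
    cand = np.unique(scores)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    best_j, best_c = -np.inf, cand[0]
    for c in cand:
        called = scores >= c
        sens = np.sum(called & labels) / n_pos
        spec = np.sum(~called & ~labels) / n_neg
        j = sens + spec - 1.0
        if j > best_j:                 # strict: ties keep the smaller cutoff
            best_j, best_c = j, c
    if best_j <= 0:
        return float(np.median(scores)), "uninformative scores; median cutoff"
    return float(best_c), ""


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class CascadeLayer:
    index: int
    panel: list
    coefficients: np.ndarray
    intercept: float
    cutoff: float
    positive_class: str                # semantics of score >= cutoff
    negative_label: str                # terminal label when routed out here
    lambda_: float = float("nan")
    rule: str = ""

    def score(self, row: pd.Series | pd.DataFrame) -> np.ndarray:
        frame = row.to_frame().T if isinstance(row, pd.Series) else row
        missing = [f for f in self.panel if f not in frame.columns]
        if missing:
            raise ValueError(f"layer {self.index} panel features missing: "
                             f"{missing[:5]}")
        X = frame[self.panel].to_numpy(dtype=float)
        return expit(self.intercept + X @ self.coefficients)

    def to_dict(self) -> dict:
        return {"index": self.index, "panel": list(map(str, self.panel)),
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept, "cutoff": self.cutoff,
                "positive_class": self.positive_class,
                "negative_label": self.negative_label,
                "lambda": self.lambda_, "rule": self.rule}

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeLayer":
        return cls(index=d["index"], panel=list(d["panel"]),
                   coefficients=np.asarray(d["coefficients"], dtype=float),
                   intercept=float(d["intercept"]), cutoff=float(d["cutoff"]),
                   positive_class=d["positive_class"],
                   negative_label=d["negative_label"],
                   lambda_=float(d.get("lambda", float("nan"))),
                   rule=d.get("rule", ""))


@dataclass
class PredictionTrace:
    sample_id: str
    scores: list                       # scores of the layers reached
    terminal_label: str
    stopped_at_layer: int


@dataclass
class CascadeModel:
    layers: list                       # three CascadeLayer, in order
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"layers": [l.to_dict() for l in self.layers],
                              "provenance": self.provenance}, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CascadeModel":
        text = (Path(source).read_text()
                if isinstance(source, Path) or "\n" not in str(source)
                and Path(str(source)).exists() else str(source))
        d = json.loads(text)
        return cls(layers=[CascadeLayer.from_dict(l) for l in d["layers"]],
                   provenance=d.get("provenance", {}))


# ---------------------------------------------------------------------------
# fitting and prediction
# ---------------------------------------------------------------------------

#: per layer: (positive side = classes routed onward or called positive,
#: label assigned on the negative side)
_LAYER_PLAN = (
    (("T2DM", "GREY", "EARLY_DKD", "OVERT_DKD"), "HC", "disease"),
    (("GREY", "EARLY_DKD", "OVERT_DKD"), "T2DM", "DKD"),
    (("EARLY_DKD",), "DKD_OTHER", "EARLY_DKD"),
)


def fit_cascade(matrix: pd.DataFrame, labels: pd.Series, folds: int = 10,
                lambda_rule: str = "1se", cutoff_method: str = "youden",
                seed: int = 0, survivor_training: bool = False) -> CascadeModel:
    """Train the three-layer cascade on discovery data.

    Layer 1: HC vs all patients; layer 2: T2DM vs kidney disease
    (grey-zone + early + overt); layer 3: early DKD vs the other
    kidney-disease classes.  By default each layer trains on the true
    labels of its in-scope classes (avoiding training-time error
    propagation); ``survivor_training=True`` instead trains layers 2-3
    only on samples the earlier layers routed onward.  Per-layer cutoffs
    are chosen on the training scores (Youden by default).
    """
    labels = labels.reindex(matrix.index)
    present = set(labels.unique())
    needed = {"HC", "T2DM", "GREY", "EARLY_DKD", "OVERT_DKD"}
    if not needed <= present:
        raise ValueError(f"missing classes in discovery data: "
                         f"{sorted(needed - present)}")

    layers = []
    surviving = matrix.index
    for li, (pos_classes, neg_label, pos_name) in enumerate(_LAYER_PLAN, 1):
        scope = pos_classes + ((neg_label,) if li < 3 else ("GREY", "OVERT_DKD"))
        if li == 1:
            scope = ("HC", "T2DM", "GREY", "EARLY_DKD", "OVERT_DKD")
        ids = labels.index[labels.isin(scope)]
        if survivor_training:
            ids = ids.intersection(surviving)
        sub = matrix.loc[ids]
        y = labels.loc[ids].isin(pos_classes)
        if y.sum() < 2 or (~y).sum() < 2:
            raise ValueError(f"layer {li}: fewer than 2 samples on one side")
        try:
            panel, coef, intercept, info = select_panel_lasso(
                sub, y.to_numpy(), folds=folds, lambda_rule=lambda_rule,
                seed=seed + li)
        except ValueError:
            # the CV band reached the intercept-only model; retry with the
            # min-deviance rule, then with the strongest nonempty penalty
            try:
                if lambda_rule == "min":
                    raise ValueError
                panel, coef, intercept, info = select_panel_lasso(
                    sub, y.to_numpy(), folds=folds, lambda_rule="min",
                    seed=seed + li)
            except ValueError:
                panel, coef, intercept, info = select_panel_lasso(
                    sub, y.to_numpy(), folds=folds,
                    lambda_rule="nonempty_max", seed=seed + li)
        layer = CascadeLayer(
            index=li, panel=panel, coefficients=coef, intercept=intercept,
            cutoff=0.5, positive_class=pos_name, negative_label=neg_label,
            lambda_=info["lambda"], rule=info["rule"])
        scores = layer.score(sub)
        cutoff, note = choose_cutoff(scores, y.to_numpy(),
                                     method=cutoff_method)
        layer.cutoff = float(cutoff)
        layers.append(layer)
        if survivor_training:
            surviving = ids[scores >= layer.cutoff]

    return CascadeModel(layers=layers, provenance={
        "seed": seed, "folds": folds, "lambda_rule": lambda_rule,
        "cutoff_method": cutoff_method,
        "n_discovery": int(matrix.shape[0]),
        "panel_sizes": [len(l.panel) for l in layers],
    })


def predict_cascade(model: CascadeModel, matrix: pd.DataFrame) -> list:
    """Route samples through the cascade; one trace per sample.

    A sample stops at the first layer whose score is below that layer's
    cutoff (scores exactly at a cutoff are routed positive) and receives
    the layer's negative label; a sample passing layer 3's cutoff is
    called EARLY_DKD, otherwise DKD_OTHER.
    """
    frame = matrix.to_frame().T if isinstance(matrix, pd.Series) else matrix
    traces = []
    for sid, row in frame.iterrows():
        scores: list[float] = []
        label = None
        for layer in model.layers:
            s = float(layer.score(row)[0])
            scores.append(s)
            if layer.index < 3:
                if s < layer.cutoff:
                    label = layer.negative_label
                    break
            else:
                label = "EARLY_DKD" if s >= layer.cutoff else "DKD_OTHER"
        traces.append(PredictionTrace(sample_id=str(sid), scores=scores,
                                      terminal_label=label,
                                      stopped_at_layer=len(scores)))
    return traces


def predictions_frame(traces: Sequence[PredictionTrace]) -> pd.DataFrame:
    rows = []
    for t in traces:
        rows.append({
            "sample_id": t.sample_id,
            "score1": t.scores[0] if len(t.scores) > 0 else float("nan"),
            "score2": t.scores[1] if len(t.scores) > 1 else float("nan"),
            "score3": t.scores[2] if len(t.scores) > 2 else float("nan"),
            "terminal_label": t.terminal_label,
            "stopped_at_layer": t.stopped_at_layer,
        })
    return pd.DataFrame(rows).set_index("sample_id")


def terminal_class_of(group: str) -> str:
    """Map a true five-class group to its cascade terminal class."""
    return {"HC": "HC", "T2DM": "T2DM", "EARLY_DKD": "EARLY_DKD",
            "GREY": "DKD_OTHER", "OVERT_DKD": "DKD_OTHER"}[group]


def grey_zone_report(model: CascadeModel, matrix: pd.DataFrame,
                     labels: pd.Series) -> dict:
    """Routing table per true group plus grey-zone discrimination.

    ``grey_routed_past_layer2`` is the fraction of grey-zone samples
    scored past layer 2, i.e. recognized as kidney disease rather than
    T2DM — the quantity behind the grey-zone discrimination claim.
    """
    labels = labels.reindex(matrix.index)
    if not (labels == "GREY").any():
        raise ValueError("no GREY samples present")
    traces = predict_cascade(model, matrix)
    pred = predictions_frame(traces)
    pred["group"] = labels.to_numpy()

    table = {}
    for g, grp in pred.groupby("group"):
        table[g] = grp["terminal_label"].value_counts(normalize=True).to_dict()

    grey = pred[pred["group"] == "GREY"]
    past2 = float(np.mean(
        (grey["stopped_at_layer"] >= 3)
        | ((grey["stopped_at_layer"] == 2)
           & (grey["terminal_label"] != "T2DM"))))
    return {"routing_table": table, "grey_routed_past_layer2": past2,
            "n_grey": int(grey.shape[0])}
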