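"""Differential feature discovery and clinical correlation screening.

Per-feature two-sample t-tests on log2 intensities with Benjamini-
Hochberg FDR control, the stepwise-feature intersection over a family of
pairwise group contrasts (the Venn-diagram construction), and a feature x
clinical-covariate correlation screen with an |r| flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ttest_features",
    "bh_adjust",
    "StepwiseFeatureSet",
    "stepwise_intersection",
    "clinical_correlation",
]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.  Rejects inputs
    outside (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ttest_features(matrix: pd.DataFrame, group_a_ids: Sequence,
                   group_b_ids: Sequence, equal_var: bool = False,
                   log_input: bool = False,
                   contrast: str = "") -> pd.DataFrame:
    """Per-feature two-sample t-test between two sample groups.

    Tests run on log2 intensities (``log_input=True`` if the matrix is
    already logged); the fold change is the difference of group mean log2
    intensities (B minus A).  Welch's unequal-variance statistic is the
    default (``equal_var=True`` for the pooled Student form).  Features
    with zero variance in both groups get p = 1 when the means agree and
    are flagged degenerate with p ~ 0 otherwise.

    Returns a frame indexed by feature with columns
    ``log2fc, t_stat, p, q, contrast, degenerate``.
    """
    a = matrix.loc[list(group_a_ids)].to_numpy(dtype=float)
    b = matrix.loc[list(group_b_ids)].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 samples per group")
    if not log_input:
        if np.nanmin(a) <= 0 or np.nanmin(b) <= 0:
            raise ValueError("intensities must be positive for log2 transform")
        a, b = np.log2(a), np.log2(b)

    mean_a, mean_b = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
    log2fc = mean_b - mean_a

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=0, equal_var=equal_var,
                              nan_policy="omit")
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    var_a = np.nanvar(a, axis=0)
    var_b = np.nanvar(b, axis=0)
    degenerate = (var_a == 0) & (var_b == 0)
    same = degenerate & np.isclose(mean_a, mean_b)
    p = np.where(same, 1.0, p)
    t = np.where(same, 0.0, t)
    diff = degenerate & ~same
    p = np.where(diff, np.nextafter(0, 1), p)
    t = np.where(diff, np.sign(log2fc) * np.inf, t)

    q = bh_adjust(np.clip(p, np.nextafter(0, 1), 1.0))
    return pd.DataFrame({
        "log2fc": log2fc, "t_stat": t, "p": p, "q": q,
        "contrast": contrast, "degenerate": diff,
    }, index=matrix.columns.rename("feature_id"))


@dataclass
class StepwiseFeatureSet:
    """Features significant in every contrast of a family, with directions."""

    features: set
    directions: pd.DataFrame          # feature x contrast, sign of log2fc
    venn_counts: dict                 # membership pattern -> count
    q_threshold: float
    monotone_features: set = field(default_factory=set)


def stepwise_intersection(results: Sequence[pd.DataFrame],
                          q_threshold: float = 0.05,
                          require_monotone: bool = False) -> StepwiseFeatureSet:
    """Intersect the per-contrast significant sets (strict q < threshold).

    ``results`` are ``ttest_features`` frames for an ordered family of
    pairwise contrasts (e.g. HC:T2DM, T2DM:EARLY_DKD, EARLY_DKD:OVERT_DKD).
    Also reports Venn region counts over the contrasts' significant sets
    and, optionally, restricts to features whose fold-change sign is
    identical in every contrast (the monotone-progression reading of
    "stepwise regulated").
    """
    if not results:
        raise ValueError("need at least one contrast result")
    names = []
    for i, r in enumerate(results):
        label = r["contrast"].iloc[0] if len(r) and r["contrast"].iloc[0] else str(i)
        names.append(label)

    sig_sets = [set(r.index[r["q"] < q_threshold]) for r in results]
    inter = set.intersection(*sig_sets)

    venn: dict[str, int] = {}
    universe = set().union(*sig_sets)
    for feat in universe:
        key = "".join("1" if feat in s else "0" for s in sig_sets)
        venn[key] = venn.get(key, 0) + 1

    directions = pd.DataFrame(
        {name: np.sign(r["log2fc"]) for name, r in zip(names, results)}
    )
    monotone = {
        f for f in inter
        if directions.loc[f].nunique() == 1 and directions.loc[f].iloc[0] != 0
    }
    features = monotone if require_monotone else inter
    return StepwiseFeatureSet(
        features=features, directions=directions.loc[sorted(universe & set(directions.index))],
        venn_counts=venn, q_threshold=q_threshold, monotone_features=monotone,
    )


def clinical_correlation(matrix: pd.DataFrame, covariates: pd.DataFrame,
                         method: str = "spearman",
                         r_threshold: float = 0.3) -> pd.DataFrame:
    """Feature x covariate correlation screen.

    Returns a long frame (feature_id, covariate, r, p, flagged) where
    ``flagged`` marks |r| > ``r_threshold``.  Constant covariates give
    undefined r (NaN) and are flagged invalid rather than raising.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    common = matrix.index.intersection(covariates.index)
    if len(common) < 4:
        raise ValueError("need >= 4 overlapping samples")
    X = matrix.loc[common]
    C = covariates.loc[common]

    rows = []
    for cov in C.columns:
        c = C[cov].to_numpy(dtype=float)
        constant = np.nanstd(c) == 0
        for feat in X.columns:
            x = X[feat].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(c)
            if constant or ok.sum() < 4:
                r, p = float("nan"), float("nan")
            else:
                r, p = corr(x[ok], c[ok])
            rows.append({"feature_id": feat, "covariate": cov,
                         "r": float(r), "p": float(p),
                         "flagged": bool(np.isfinite(r) and abs(r) > r_threshold)})
    return pd.DataFrame(rows)
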