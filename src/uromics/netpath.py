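"""Correlation networks and pathway perturbation scoring.

Biweight midcorrelation (a robust, median/MAD-based correlation with
Tukey biweights) feature-feature networks per clinical group, a signed
Stouffer-type pathway perturbation ("JG") score aggregating member-level
fold-change direction and significance, and one-sided hypergeometric
pathway enrichment — single-namespace or joint across metabolites and
peptide-source proteins — on user-supplied GMT annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_adjust

__all__ = [
    "bicor",
    "bicor_pvalue",
    "correlation_network",
    "jg_score",
    "read_gmt",
    "enrich_hypergeometric",
    "joint_enrichment",
]

_Z_CAP_P = 1e-300


def _biweight(x: np.ndarray):
    """Tukey biweight-transformed deviations around the median.

    Returns the weighted, normalized deviations a_i such that
    bicor(x, y) = sum a_i b_i, or None when MAD = 0 (constant-heavy
    vector) so the caller can fall back to Pearson.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
    num = (x - med) * w
    denom = np.sqrt(np.sum(num * num))
    if denom == 0:
        return None
    return num / denom


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors (in [-1, 1]).

    Deviations from the median are weighted by (1-u^2)^2 for |u| < 1 with
    u = deviation / (9 * MAD), then cross-multiplied and normalized.
    Falls back to Pearson (with a warning-free flagged contract) when a
    vector's MAD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    a = _biweight(x)
    b = _biweight(y)
    if a is None or b is None:
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("constant vector; correlation undefined")
        return float(np.clip(stats.pearsonr(x, y).statistic, -1.0, 1.0))
    return float(np.clip(np.sum(a * b), -1.0, 1.0))


def bicor_pvalue(r: float, n: int) -> float:
    """Two-sided p-value via the Student-t approximation with n-2 df."""
    if n < 3:
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlation_network(matrix: pd.DataFrame, group_ids: Sequence,
                        features: Sequence[str] | None = None,
                        r_threshold: float = 0.3,
                        p_threshold: float = 0.05) -> dict:
    """All-pairs bicor network among selected features within one group.

    Returns ``{"edges": frame(feature_a, feature_b, r, p, sign),
    "n_positive", "n_negative", "n_samples"}``; edges must satisfy both
    |r| > ``r_threshold`` and p < ``p_threshold``.
    """
    sub = matrix.loc[list(group_ids)]
    if sub.shape[0] < 4:
        raise ValueError("need >= 4 samples in the group")
    if features is not None:
        sub = sub[list(features)]
    n = sub.shape[0]
    cols = list(sub.columns)
    rows = []
    values = {c: sub[c].to_numpy(dtype=float) for c in cols}
    for fa, fb in combinations(cols, 2):
        r = bicor(values[fa], values[fb])
        p = bicor_pvalue(r, n)
        if abs(r) > r_threshold and p < p_threshold:
            rows.append({"feature_a": fa, "feature_b": fb, "r": r, "p": p,
                         "sign": int(np.sign(r))})
    edges = pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p",
                                        "sign"])
    return {
        "edges": edges,
        "n_positive": int((edges["sign"] > 0).sum()) if len(edges) else 0,
        "n_negative": int((edges["sign"] < 0).sum()) if len(edges) else 0,
        "n_samples": n,
    }


# ---------------------------------------------------------------------------
# pathway scores
# ---------------------------------------------------------------------------

def jg_score(log2fc: Sequence[float], pvalues: Sequence[float]) -> float:
    """Signed Stouffer-type pathway perturbation score.

    Each member contributes z_i = sign(log2fc_i) * |probit(p_i / 2)| —
    its two-sided p mapped to a signed normal quantile — and the score is
    sum(z) / sqrt(k) for k members, so coherent perturbation grows as
    sqrt(k) while balanced up/down changes cancel.  p = 0 is capped at
    1e-300.
    """
    fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    if fc.shape != p.shape or fc.size == 0:
        raise ValueError("need equal-length, non-empty member stats")
    if np.any(~np.isfinite(fc)) or np.any(~np.isfinite(p)):
        raise ValueError("member stats must be finite")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, _Z_CAP_P, 1.0)
    z = np.sign(fc) * np.abs(stats.norm.ppf(p / 2.0))
    return float(np.sum(z) / np.sqrt(fc.size))


def read_gmt(path: str | Path) -> dict:
    """Parse a GMT file: one ``name<TAB>description<TAB>member...`` line
    per pathway; returns {name: set of members}."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


@dataclass
class PathwayScore:
    pathway: str
    p: float
    q: float
    k: int                              # selected members found
    K: int                              # pathway size within the universe
    n: int                              # selection size
    N: int                              # universe size
    members_found: list = field(default_factory=list)
    jg: float | None = None

    def to_dict(self) -> dict:
        return {"pathway": self.pathway, "p": self.p, "q": self.q,
                "k": self.k, "K": self.K, "n": self.n, "N": self.N,
                "members_found": self.members_found, "jg": self.jg}


def enrich_hypergeometric(selected: Sequence[str],
                          pathway_sets: Mapping[str, set],
                          universe: Sequence[str],
                          member_stats: pd.DataFrame | None = None) -> list:
    """One-sided hypergeometric upper-tail enrichment per pathway.

    Pathway members are intersected with the universe; p = P(X >= k) for
    X ~ Hypergeom(N, K, n) with N = |universe|, K = pathway members in
    the universe, n = |selected|, k = overlap.  BH adjustment across
    pathways.  With ``member_stats`` (frame indexed by feature with
    ``log2fc`` and ``p`` columns) each pathway also carries its JG score
    over the selected members found.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected features must be a subset of the universe")
    N, n = len(universe), len(selected)
    out = []
    for name, members in pathway_sets.items():
        in_uni = members & universe
        K = len(in_uni)
        found = sorted(in_uni & selected)
        k = len(found)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        jg = None
        if member_stats is not None and found:
            sub = member_stats.loc[[f for f in found
                                    if f in member_stats.index]]
            if len(sub):
                jg = jg_score(sub["log2fc"].to_numpy(), sub["p"].to_numpy())
        out.append(PathwayScore(pathway=name, p=min(p, 1.0), q=1.0, k=k, K=K,
                                n=n, N=N, members_found=found, jg=jg))
    if out:
        qs = bh_adjust([max(s.p, np.nextafter(0, 1)) for s in out])
        for s, q in zip(out, qs):
            s.q = float(q)
    return out


def joint_enrichment(metabolite_hits: Sequence[str],
                     protein_hits: Sequence[str],
                     joint_pathway_sets: Mapping[str, set],
                     metabolite_universe: Sequence[str],
                     protein_universe: Sequence[str]) -> list:
    """Joint metabolite + peptide-source-protein enrichment.

    Pools the two namespaces into one union universe and runs the same
    hypergeometric test; a pathway may be hit through either entity type
    alone.  With no cross-type pathways the results coincide with the
    two separate single-namespace analyses.
    """
    met_u, prot_u = set(metabolite_universe), set(protein_universe)
    if met_u & prot_u:
        raise ValueError("metabolite and protein namespaces overlap")
    universe = met_u | prot_u
    selected = set(metabolite_hits) | set(protein_hits)
    return enrich_hypergeometric(selected, joint_pathway_sets, universe)
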