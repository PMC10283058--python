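"""Spectral preprocessing and platform QC.

Turns raw traces or replicate-level peak tables into one normalized
feature matrix: S/N > 3 peak picking with a robust (sliding-window MAD)
noise estimate, m/z alignment across samples, cubic-spline quantile
normalization, replicate averaging, and the platform quality-control
report (technical-replicate Spearman concordance, intra-/inter-batch RSD
and internal-standard ratio stability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "Peak",
    "PeakList",
    "QCReport",
    "pick_peaks",
    "align_features",
    "cubic_spline_normalize",
    "filter_and_impute",
    "average_replicates",
    "qc_report",
]

#: default alignment tolerances: absolute Da for the reflector-mode
#: metabolite window, mass-proportional ppm for the linear-mode peptides
DEFAULT_TOLERANCE = {"metabolite": ("da", 0.05), "peptide": ("ppm", 500.0)}


@dataclass
class Spectrum:
    """One raw trace: an ascending m/z grid and non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate: int = 1
    modality: str = "metabolite"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")


@dataclass
class Peak:
    mz: float
    intensity: float
    snr: float


@dataclass
class PeakList:
    peaks: list
    sample_id: str = ""
    replicate: int = 1
    modality: str = "metabolite"

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class QCReport:
    replicate_spearman: float
    intra_batch_rsd_median: float
    inter_batch_rsd_median: float
    internal_standard_ratio_rsd: float
    pass_flags: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "replicate_spearman": self.replicate_spearman,
            "intra_batch_rsd_median": self.intra_batch_rsd_median,
            "inter_batch_rsd_median": self.inter_batch_rsd_median,
            "internal_standard_ratio_rsd": self.internal_standard_ratio_rsd,
            "pass_flags": self.pass_flags,
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# peak picking
# ---------------------------------------------------------------------------

def local_baseline_and_noise(intensity: np.ndarray, window: int = 101):
    """Robust local baseline (median) and noise (1.4826 x MAD) per point.

    Both are computed in a centred window clipped at the trace edges (no
    padding), which keeps the estimates well-defined on the first and
    last points and robust to peaks inside the window.
    """
    y = np.asarray(intensity, dtype=float)
    n = y.size
    base = np.empty(n)
    noise = np.empty(n)
    if n == 0:
        return base, noise
    h = window // 2
    if n >= window:
        sw = np.lib.stride_tricks.sliding_window_view(y, window)
        med = np.median(sw, axis=1)
        mad = np.median(np.abs(sw - med[:, None]), axis=1)
        base[h:n - h] = med
        noise[h:n - h] = 1.4826 * mad
        edge = list(range(h)) + list(range(n - h, n))
    else:
        edge = range(n)
    for i in edge:
        seg = y[max(0, i - h): i + h + 1]
        med = np.median(seg)
        base[i] = med
        noise[i] = 1.4826 * np.median(np.abs(seg - med))
    return base, noise


def pick_peaks(spectrum: Spectrum, snr_threshold: float = 3.0,
               window: int = 101) -> PeakList:
    """Pick local maxima with S/N above ``snr_threshold``.

    A point is a peak when it is a strict local maximum of the trace and
    its height above the local baseline exceeds ``snr_threshold`` x the
    local noise scale, with baseline = sliding-window median and noise =
    1.4826 x sliding-window MAD (the field's standard baseline-relative
    S/N).  Empty and constant traces yield an empty peak list; lowering
    the threshold can only add peaks.
    """
    y = spectrum.intensity
    if y.size < 3:
        return PeakList([], spectrum.sample_id, spectrum.replicate,
                        spectrum.modality)
    base, noise = local_baseline_and_noise(y, window=window)
    interior = np.arange(1, y.size - 1)
    is_max = (y[interior] > y[interior - 1]) & (y[interior] > y[interior + 1])
    cand = interior[is_max]
    height = y[cand] - base[cand]
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise[cand] > 0,
                       height / noise[cand],
                       np.where(height > 0, np.inf, 0.0))
    keep = cand[snr > snr_threshold]
    keep_snr = snr[snr > snr_threshold]
    peaks = [Peak(float(spectrum.mz[i]), float(y[i]), float(s))
             for i, s in zip(keep, keep_snr)]
    return PeakList(peaks, spectrum.sample_id, spectrum.replicate,
                    spectrum.modality)


# ---------------------------------------------------------------------------
# feature alignment
# ---------------------------------------------------------------------------

def align_features(peaklists: Sequence[PeakList],
                   tolerance: float = 0.05,
                   unit: str = "da") -> pd.DataFrame:
    """Cluster peaks across samples into consensus features.

    Peaks are pooled, sorted by m/z and split wherever the gap between
    neighbours exceeds the tolerance — i.e. single-linkage clustering with
    a distance cutoff.  With ``unit='ppm'`` the cutoff is mass-
    proportional.  Returns a (sample_replicate x feature) intensity frame;
    a position where a sample contributed no peak is missing (NaN); if a
    sample contributes several peaks to one cluster the most intense is
    kept, so each input peak maps to at most one feature.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if unit not in ("da", "ppm"):
        raise ValueError("unit must be 'da' or 'ppm'")
    if not peaklists:
        raise ValueError("need at least one peak list")

    rows, mzs, intens = [], [], []
    row_ids = []
    for pl in peaklists:
        rid = f"{pl.sample_id}_r{pl.replicate}"
        if rid not in row_ids:
            row_ids.append(rid)
        for p in pl.peaks:
            rows.append(rid)
            mzs.append(p.mz)
            intens.append(p.intensity)
    if not mzs:
        return pd.DataFrame(index=pd.Index(row_ids, name="sample_replicate"))

    mzs = np.asarray(mzs)
    intens = np.asarray(intens)
    rows = np.asarray(rows)
    order = np.argsort(mzs, kind="stable")
    mzs_s, intens_s, rows_s = mzs[order], intens[order], rows[order]

    gaps = np.diff(mzs_s)
    cut = gaps > (tolerance if unit == "da"
                  else tolerance * 1e-6 * mzs_s[:-1])
    labels = np.concatenate([[0], np.cumsum(cut)])

    modality = peaklists[0].modality
    prefix = "met" if modality == "metabolite" else "pep"
    fmt = "{}_{:.4f}" if modality == "metabolite" else "{}_{:.2f}"

    data: dict[str, dict[str, float]] = {}
    for lab in range(labels[-1] + 1):
        sel = labels == lab
        consensus = float(mzs_s[sel].mean())
        fid = fmt.format(prefix, consensus)
        col = data.setdefault(fid, {})
        for rid, it in zip(rows_s[sel], intens_s[sel]):
            col[rid] = max(col.get(rid, -np.inf), float(it))
    frame = pd.DataFrame(data, index=pd.Index(row_ids, name="sample_replicate"))
    return frame


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _log_quantiles(values: np.ndarray, probs: np.ndarray) -> np.ndarray:
    # order-statistic quantiles commute with monotone maps, which makes
    # renormalization an exact no-op
    return np.quantile(values, probs, method="lower")


def cubic_spline_normalize(matrix: pd.DataFrame,
                           reference: str | pd.Series = "median_all",
                           qc_ids: Iterable[str] | None = None,
                           n_interior_knots: int = 7) -> pd.DataFrame:
    """Quantile-targeted cubic-spline intensity normalization.

    For each sample a smooth monotone cubic mapping (a PCHIP spline,
    guaranteeing rank preservation) is fitted on the log2 scale between
    the sample's intensity quantiles and the reference's quantiles, with
    knots at evenly spaced probabilities, and applied to every observed
    intensity.  The reference is the per-feature median over all samples
    (``"median_all"``), over QC rows (``"median_qc"`` with ``qc_ids``), or
    an explicit per-feature Series.  A sample with fewer observed values
    than knots falls back to median scaling (logged).  The operation is
    idempotent: renormalizing against the same reference is a no-op.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples to normalize")
    if isinstance(reference, pd.Series):
        ref_values = reference.reindex(matrix.columns).to_numpy(dtype=float)
    elif reference == "median_all":
        ref_values = matrix.median(axis=0, skipna=True).to_numpy()
    elif reference == "median_qc":
        if not qc_ids:
            raise ValueError("median_qc reference requires qc_ids")
        qc_rows = matrix.loc[list(qc_ids)]
        ref_values = qc_rows.median(axis=0, skipna=True).to_numpy()
    else:
        raise ValueError(f"unknown reference {reference!r}")

    ref_values = ref_values[np.isfinite(ref_values)]
    if ref_values.size == 0 or np.any(ref_values <= 0):
        raise ValueError("reference must be strictly positive")

    probs = np.linspace(0.0, 1.0, n_interior_knots + 2)
    ref_q = np.log2(_log_quantiles(ref_values, probs))

    out = matrix.copy().astype(float)
    X = out.to_numpy()
    for i in range(X.shape[0]):
        row = X[i]
        obs = np.isfinite(row)
        vals = row[obs]
        if vals.size < n_interior_knots + 2:
            scale = np.median(ref_values) / np.median(vals)
            logger.info("sample %s: %d observed features < %d knots; "
                        "median scaling fallback", out.index[i], vals.size,
                        n_interior_knots + 2)
            X[i, obs] = vals * scale
            continue
        smp_q = np.log2(_log_quantiles(vals, probs))
        # collapse duplicate knot abscissae (ties in the quantile curve)
        keep = np.concatenate([[True], np.diff(smp_q) > 0])
        xs, ys = smp_q[keep], ref_q[keep]
        if xs.size < 2:
            scale = np.median(ref_values) / np.median(vals)
            X[i, obs] = vals * scale
            continue
        spline = PchipInterpolator(xs, ys, extrapolate=True)
        X[i, obs] = np.exp2(spline(np.log2(vals)))
    out.loc[:, :] = X
    return out


def filter_and_impute(matrix: pd.DataFrame, min_presence: float = 0.7,
                      impute: str = "half_min") -> pd.DataFrame:
    """Keep features observed in >= ``min_presence`` of rows; impute the
    rest with half the feature's minimum observed value."""
    present = matrix.notna().mean(axis=0)
    kept = matrix.loc[:, present >= min_presence].copy()
    if impute == "half_min":
        fill = kept.min(axis=0, skipna=True) / 2.0
        kept = kept.fillna(fill)
    elif impute != "none":
        raise ValueError(f"unknown imputation {impute!r}")
    return kept


def average_replicates(matrix: pd.DataFrame,
                       replicate_map: pd.Series | None = None) -> pd.DataFrame:
    """Average replicate rows into one row per biological sample.

    ``replicate_map`` maps each row id to its sample id; with a
    (sample_id, replicate) MultiIndex it may be omitted.  Missing values
    are ignored in the mean; a feature missing in every replicate of a
    sample stays missing.
    """
    if replicate_map is None:
        if isinstance(matrix.index, pd.MultiIndex):
            groups = matrix.index.get_level_values(0)
        else:
            raise ValueError("replicate_map required for a flat index")
    else:
        missing = [i for i in matrix.index if i not in replicate_map.index]
        if missing:
            raise ValueError(f"replicate_map lacks rows: {missing[:5]}")
        groups = replicate_map.reindex(matrix.index).to_numpy()
    out = matrix.groupby(groups, sort=False).mean()
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------

def _rsd_percent(values: np.ndarray) -> np.ndarray:
    """Per-feature RSD (%) over rows: 100 * sample SD / mean."""
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 100.0 * sd / mean


def qc_report(matrix: pd.DataFrame, qc_ids: Sequence,
              internal_standard_ids: Sequence[str] | None = None,
              batch_labels: pd.Series | None = None,
              spearman_min: float = 0.8, rsd_max: float = 25.0) -> QCReport:
    """Platform reproducibility metrics from QC replicate rows.

    * ``replicate_spearman`` — mean Spearman rank correlation over all
      pairs of QC replicate rows (undefined, NaN + flag, with < 2 rows);
    * ``intra_batch_rsd_median`` — median over features of the per-feature
      RSD of QC rows within a batch, pooled across batches;
    * ``inter_batch_rsd_median`` — median per-feature RSD of the per-batch
      QC means (needs >= 2 batches);
    * ``internal_standard_ratio_rsd`` — RSD of the ratio of the two
      internal-standard channels over all rows of ``matrix``.
    """
    notes: list[str] = []
    qc_rows = matrix.loc[list(qc_ids)]
    if qc_rows.shape[0] < 2:
        notes.append("fewer than 2 QC replicates; Spearman undefined")
        spearman = float("nan")
    else:
        vals = qc_rows.to_numpy()
        cors = []
        for i in range(vals.shape[0]):
            for j in range(i + 1, vals.shape[0]):
                ok = np.isfinite(vals[i]) & np.isfinite(vals[j])
                if ok.sum() >= 3:
                    cors.append(stats.spearmanr(vals[i][ok], vals[j][ok]).statistic)
        spearman = float(np.mean(cors)) if cors else float("nan")

    if batch_labels is not None:
        qc_batches = batch_labels.reindex(qc_rows.index)
        intra = []
        batch_means = []
        for _, grp in qc_rows.groupby(qc_batches.to_numpy()):
            if grp.shape[0] >= 2:
                intra.append(_rsd_percent(grp.to_numpy()))
            batch_means.append(np.nanmean(grp.to_numpy(), axis=0))
        intra_med = (float(np.nanmedian(np.concatenate(intra)))
                     if intra else float("nan"))
        if len(batch_means) >= 2:
            inter_med = float(np.nanmedian(_rsd_percent(np.vstack(batch_means))))
        else:
            inter_med = float("nan")
            notes.append("fewer than 2 batches; inter-batch RSD undefined")
    else:
        intra_med = float(np.nanmedian(_rsd_percent(qc_rows.to_numpy())))
        inter_med = float("nan")
        notes.append("no batch labels; all QC rows treated as one batch")

    if internal_standard_ids and len(internal_standard_ids) == 2:
        a, b = internal_standard_ids
        ratio = (matrix[a] / matrix[b]).to_numpy()
        ratio = ratio[np.isfinite(ratio)]
        is_rsd = float(100.0 * np.std(ratio, ddof=1) / np.mean(ratio))
    else:
        is_rsd = float("nan")
        notes.append("internal-standard ratio not computed")

    flags = {
        "replicate_spearman": bool(spearman >= spearman_min)
        if np.isfinite(spearman) else False,
        "intra_batch_rsd": bool(intra_med <= rsd_max)
        if np.isfinite(intra_med) else False,
        "internal_standard_ratio_rsd": bool(is_rsd <= rsd_max)
        if np.isfinite(is_rsd) else False,
    }
    return QCReport(
        replicate_spearman=spearman,
        intra_batch_rsd_median=intra_med,
        inter_batch_rsd_median=inter_med,
        internal_standard_ratio_rsd=is_rsd,
        pass_flags=flags, notes=notes,
    )
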