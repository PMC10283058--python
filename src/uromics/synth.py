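"""Synthetic urine multi-omics cohorts.

Generates cohorts with the statistical structure the downstream analysis
assumes: five clinical classes (healthy controls, type-2 diabetics without
albuminuria, grey-zone patients, early and overt diabetic kidney disease),
two modalities (a low-mass metabolite fingerprint and a high-mass peptide
profile), a planted subset of monotonically stepwise-regulated features,
technical replicates, batch structure, two internal-standard channels and
clinical covariates obeying the KDIGO albuminuria categories.

Intensity model: log2-normal.  For sample *s*, replicate *r*, feature *f*,

    log2 I = baseline_f + group_shift_f(class_s) + bio_fs + batch_fb + eps_fsr

where ``bio`` is a per-subject biological deviation (zero for the internal
standards), ``batch`` a per-feature per-batch shift and ``eps`` technical
noise whose standard deviation is derived from the configured linear-scale
coefficient of variation, so that the technical CV is exact by construction.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GROUPS",
    "CohortConfig",
    "SampleRecord",
    "FeatureSpec",
    "SyntheticCohort",
    "SpectraConfig",
    "generate_clinical",
    "generate_cohort",
    "emit_spectra",
]

#: The five clinical classes, in disease-stage order (GREY sits between
#: T2DM and EARLY_DKD biologically but is listed last-but-two for clarity).
GROUPS = ("HC", "T2DM", "GREY", "EARLY_DKD", "OVERT_DKD")

#: Stage index used for stepwise shifts: HC=0, T2DM=1, EARLY=2, OVERT=3.
#: GREY is placed between T2DM and EARLY at a configurable fraction.
_STAGE = {"HC": 0.0, "T2DM": 1.0, "EARLY_DKD": 2.0, "OVERT_DKD": 3.0}

_LN2 = math.log(2.0)


def _technical_sd_log2(cv: float) -> float:
    """log2-scale SD giving an exact linear-scale coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv)) / _LN2


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults reproduce the model-establishment study conditions: 501
    subjects (152 HC, 149 T2DM, 39 grey-zone, 106 early DKD, 55 overt DKD),
    ~227 metabolite and ~206 peptide features of which 10 metabolites and
    6 peptides are planted as stepwise regulated, three technical
    replicates, two batches.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {
            "HC": 152, "T2DM": 149, "GREY": 39, "EARLY_DKD": 106, "OVERT_DKD": 55,
        }
    )
    n_met_features: int = 227
    n_pep_features: int = 206
    n_stepwise_met: int = 10
    n_stepwise_pep: int = 6
    #: per-stage increment of the planted shift, log2 units
    effect_log2fc: float = 0.5
    #: linear-scale coefficient of variation of technical (replicate) noise
    noise_cv: float = 0.15
    n_replicates: int = 3
    n_batches: int = 2
    #: SD of the per-feature, per-batch additive log2 shift
    batch_sd_log2: float = 0.25
    #: between-subject biological SD on the log2 scale
    bio_sd_log2: float = 0.30
    #: GREY group's position between the T2DM and EARLY_DKD shifts
    grey_effect_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.n_per_group) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group counts must be non-negative")
        if sum(self.n_per_group.values()) < 1:
            raise ValueError("cohort must contain at least one sample")
        for name in ("n_met_features", "n_pep_features", "n_replicates", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.n_stepwise_met <= self.n_met_features):
            raise ValueError("n_stepwise_met must lie in [0, n_met_features]")
        if not (0 <= self.n_stepwise_pep <= self.n_pep_features):
            raise ValueError("n_stepwise_pep must lie in [0, n_pep_features]")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be > 0")
        if self.n_met_features < 3:
            raise ValueError("need >= 3 metabolite features (2 internal standards)")


@dataclass
class SampleRecord:
    """One subject with KDIGO-consistent clinical covariates."""

    sample_id: str
    group: str
    batch: int
    age: float
    sex: str
    bmi: float
    egfr: float
    uacr: float
    malb: float


@dataclass
class FeatureSpec:
    """One spectral feature and its planted regulation."""

    feature_id: str
    modality: str           # "metabolite" | "peptide"
    mz: float
    baseline_log2: float
    regulation: str         # "null" | "stepwise_up" | "stepwise_down"
    group_shifts: dict      # group -> log2 shift


@dataclass
class SyntheticCohort:
    samples: list
    feature_specs: list
    #: replicate-level intensities, MultiIndex (sample_id, replicate) x features
    intensities: pd.DataFrame
    truth: set
    internal_standard_ids: tuple
    config: CohortConfig

    @property
    def feature_ids(self) -> list:
        return list(self.intensities.columns)

    def metadata(self) -> pd.DataFrame:
        """Replicate-level metadata aligned with ``intensities`` rows."""
        rows = []
        for s in self.samples:
            for r in range(1, self.config.n_replicates + 1):
                rows.append({
                    "sample_id": s.sample_id, "replicate": r, "group": s.group,
                    "batch": s.batch, "age": s.age, "sex": s.sex, "bmi": s.bmi,
                    "egfr": s.egfr, "uacr": s.uacr, "malb": s.malb,
                })
        return pd.DataFrame(rows).set_index(["sample_id", "replicate"])

    def sample_metadata(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.samples]).set_index("sample_id")

    def modality_columns(self, modality: str) -> list:
        return [f.feature_id for f in self.feature_specs if f.modality == modality]

    def write(self, outdir: str | Path) -> None:
        """Write matrix CSV, metadata TSV and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        flat = self.intensities.copy()
        flat.index = [f"{s}_r{r}" for s, r in self.intensities.index]
        flat.index.name = "sample_replicate"
        flat.to_csv(outdir / "feature_matrix.csv")
        self.metadata().reset_index().to_csv(
            outdir / "metadata.tsv", sep="\t", index=False
        )
        truth = {
            "stepwise_features": sorted(self.truth),
            "internal_standards": list(self.internal_standard_ids),
            "directions": {
                f.feature_id: f.regulation
                for f in self.feature_specs if f.regulation != "null"
            },
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


# (mean, sd, lo, hi) per covariate per group; bounds enforce the KDIGO
# albuminuria categories: UACR in mg/mmol, mALB in mg/g, eGFR in
# ml/min/1.73 m^2.  eGFR decreases and UACR/mALB increase with stage.
_CLINICAL = {
    "HC":        {"egfr": (102, 12, 60, 140), "uacr": (0.8, 0.5, 0.05, 2.999),
                  "malb": (8, 5, 0.5, 29.9), "age": (48, 11, 25, 78),
                  "bmi": (23.0, 2.5, 17, 35)},
    "T2DM":      {"egfr": (96, 12, 60, 140), "uacr": (1.2, 0.6, 0.05, 2.999),
                  "malb": (14, 6, 0.5, 29.9), "age": (55, 10, 28, 80),
                  "bmi": (25.0, 3.0, 17, 38)},
    "GREY":      {"egfr": (92, 12, 60, 140), "uacr": (1.8, 0.6, 0.05, 2.999),
                  "malb": (48, 14, 30, 150), "age": (57, 10, 30, 80),
                  "bmi": (25.5, 3.0, 17, 38)},
    "EARLY_DKD": {"egfr": (84, 11, 60, 130), "uacr": (11, 6, 3, 29.9),
                  "malb": (110, 50, 30, 400), "age": (59, 10, 30, 82),
                  "bmi": (25.5, 3.0, 17, 38)},
    "OVERT_DKD": {"egfr": (52, 16, 15, 95), "uacr": (70, 35, 30, 250),
                  "malb": (600, 250, 300, 2000), "age": (62, 10, 32, 85),
                  "bmi": (25.0, 3.0, 17, 38)},
}


def generate_clinical(group: str, rng: np.random.Generator) -> dict:
    """Draw KDIGO-consistent clinical covariates for one subject.

    Post-conditions (enforced by truncation, so they hold for every draw):
    HC and T2DM have UACR < 3, mALB < 30 and eGFR >= 60; GREY has
    mALB >= 30 with UACR < 3 and eGFR >= 60; EARLY_DKD has 3 <= UACR < 30
    with eGFR >= 60; OVERT_DKD has UACR >= 30 (its eGFR may also fall
    below 60, satisfying the alternative criterion).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    p = _CLINICAL[group]
    return {
        "age": round(_truncnorm(rng, *p["age"]), 1),
        "sex": "F" if rng.random() < 0.5 else "M",
        "bmi": round(_truncnorm(rng, *p["bmi"]), 1),
        "egfr": round(_truncnorm(rng, *p["egfr"]), 1),
        "uacr": round(_truncnorm(rng, *p["uacr"]), 3),
        "malb": round(_truncnorm(rng, *p["malb"]), 1),
    }


# ---------------------------------------------------------------------------
# feature specifications
# ---------------------------------------------------------------------------

def _majority_split(n: int, majority_frac: float = 0.7) -> int:
    """Size of the majority block: >= ceil(n/2) when n >= 1."""
    if n == 0:
        return 0
    k = int(round(majority_frac * n))
    return max(k, n // 2 + 1)


def _stepwise_shifts(direction: str, effect: float, grey_frac: float,
                     rng: np.random.Generator) -> dict:
    """Monotone per-group shifts with feature-specific stage increments.

    Each of the three stage transitions (HC->T2DM, T2DM->EARLY_DKD,
    EARLY_DKD->OVERT_DKD) gets an increment of ``effect`` x U(0.5, 1.5),
    so shifts are monotone with mean per-stage increment ``effect`` but
    class mean profiles differ between features (as in real panels,
    where markers emphasize different stages).  GREY sits ``grey_frac``
    of the way along the T2DM -> EARLY_DKD increment.
    """
    sign = 1.0 if direction == "stepwise_up" else -1.0
    inc = effect * rng.uniform(0.5, 1.5, 3)
    cum = np.concatenate([[0.0], np.cumsum(inc)])
    shifts = {g: sign * cum[int(s)] for g, s in _STAGE.items()}
    shifts["GREY"] = sign * (cum[1] + grey_frac * inc[1])
    return shifts


def _make_feature_specs(cfg: CohortConfig, rng: np.random.Generator):
    specs: list[FeatureSpec] = []

    met_mz = np.sort(rng.uniform(20.0, 350.0, cfg.n_met_features))
    pep_mz = np.sort(rng.uniform(600.0, 20000.0, cfg.n_pep_features))

    # internal standards: two fixed metabolite channels (spiked compounds),
    # null regulation, zero biological variance.
    is_mz = (199.04, 254.09)

    n_met_down = _majority_split(cfg.n_stepwise_met)       # metabolites: mostly down
    n_pep_up = _majority_split(cfg.n_stepwise_pep)         # peptides: mostly up

    met_step_idx = rng.choice(cfg.n_met_features, cfg.n_stepwise_met, replace=False)
    pep_step_idx = rng.choice(cfg.n_pep_features, cfg.n_stepwise_pep, replace=False)

    def regulation_for(i, step_idx, n_major, major_dir, minor_dir):
        if i not in step_idx:
            return "null"
        rank = int(np.where(step_idx == i)[0][0])
        return major_dir if rank < n_major else minor_dir

    for i, mz in enumerate(met_mz):
        reg = regulation_for(i, met_step_idx, n_met_down,
                             "stepwise_down", "stepwise_up")
        specs.append(FeatureSpec(
            feature_id=f"met_{mz:.4f}", modality="metabolite", mz=float(mz),
            baseline_log2=float(rng.normal(12.0, 2.0)), regulation=reg,
            group_shifts=(_stepwise_shifts(reg, cfg.effect_log2fc,
                                           cfg.grey_effect_fraction, rng)
                          if reg != "null" else {g: 0.0 for g in GROUPS}),
        ))
    for i, mz in enumerate(pep_mz):
        reg = regulation_for(i, pep_step_idx, n_pep_up,
                             "stepwise_up", "stepwise_down")
        specs.append(FeatureSpec(
            feature_id=f"pep_{mz:.2f}", modality="peptide", mz=float(mz),
            baseline_log2=float(rng.normal(11.0, 2.0)), regulation=reg,
            group_shifts=(_stepwise_shifts(reg, cfg.effect_log2fc,
                                           cfg.grey_effect_fraction, rng)
                          if reg != "null" else {g: 0.0 for g in GROUPS}),
        ))

    is_ids = []
    for mz, base in zip(is_mz, (13.0, 12.5)):
        fid = f"met_{mz:.4f}"
        specs.append(FeatureSpec(
            feature_id=fid, modality="metabolite", mz=mz, baseline_log2=base,
            regulation="null", group_shifts={g: 0.0 for g in GROUPS},
        ))
        is_ids.append(fid)
    return specs, tuple(is_ids)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (deterministic under ``config.seed``).

    Replicate intensities follow the module-level log2-normal model.  The
    planted stepwise features are biased mostly downward for metabolites
    and mostly upward for peptides; group means of every stepwise feature
    are monotone across HC -> T2DM -> EARLY_DKD -> OVERT_DKD by
    construction, with GREY placed between T2DM and EARLY_DKD.
    """
    rng = np.random.default_rng(config.seed)

    for g in ("HC", "T2DM", "EARLY_DKD", "OVERT_DKD", "GREY"):
        if config.n_per_group.get(g, 0) == 0:
            warnings.warn(
                f"group {g} has 0 samples; downstream defaults reference it",
                stacklevel=2,
            )

    specs, is_ids = _make_feature_specs(config, rng)
    feature_ids = [f.feature_id for f in specs]
    n_feat = len(specs)

    samples: list[SampleRecord] = []
    idx = 0
    for g in GROUPS:
        for _ in range(config.n_per_group.get(g, 0)):
            idx += 1
            cov = generate_clinical(g, rng)
            samples.append(SampleRecord(
                sample_id=f"S{idx:04d}", group=g,
                batch=int(rng.integers(1, config.n_batches + 1)), **cov,
            ))

    n_samp = len(samples)
    baseline = np.array([f.baseline_log2 for f in specs])
    shifts = np.array([[f.group_shifts[s.group] for f in specs] for s in samples])

    is_mask = np.array([f.feature_id in is_ids for f in specs])

    # biological between-subject deviation; zero for the internal standards
    bio = rng.normal(0.0, config.bio_sd_log2, (n_samp, n_feat))
    bio[:, is_mask] = 0.0

    # per-feature per-batch shift; the two IS channels share one per-batch
    # instrument-sensitivity shift so their ratio cancels batch drift
    batch_shift = rng.normal(0.0, config.batch_sd_log2,
                             (config.n_batches, n_feat))
    is_common = rng.normal(0.0, config.batch_sd_log2, config.n_batches)
    batch_shift[:, is_mask] = is_common[:, None]
    batches = np.array([s.batch - 1 for s in samples])

    sd_tech = _technical_sd_log2(config.noise_cv)
    eps = rng.normal(0.0, sd_tech, (n_samp, config.n_replicates, n_feat))

    log2_mean = baseline[None, :] + shifts + bio + batch_shift[batches]
    log2_int = log2_mean[:, None, :] + eps
    inten = np.exp2(log2_int)

    index = pd.MultiIndex.from_tuples(
        [(s.sample_id, r) for s in samples
         for r in range(1, config.n_replicates + 1)],
        names=["sample_id", "replicate"],
    )
    matrix = pd.DataFrame(
        inten.reshape(n_samp * config.n_replicates, n_feat),
        index=index, columns=feature_ids,
    )

    truth = {f.feature_id for f in specs if f.regulation != "null"}
    return SyntheticCohort(
        samples=samples, feature_specs=specs, intensities=matrix,
        truth=truth, internal_standard_ids=is_ids, config=config,
    )


# ---------------------------------------------------------------------------
# spectrum emission
# ---------------------------------------------------------------------------

@dataclass
class SpectraConfig:
    """Synthetic trace parameters; defaults are order-of-magnitude for a
    reflector-mode metabolite window and a linear-mode peptide window."""

    met_range: tuple = (20.0, 350.0)
    pep_range: tuple = (600.0, 20000.0)
    met_grid_step: float = 0.01
    pep_grid_step: float = 0.5
    met_peak_width: float = 0.05     # Gaussian sigma, Da
    pep_peak_width: float = 2.0
    noise_sd: float = 1.0            # additive baseline noise SD
    baseline_offset: float = 3.0     # flat baseline level (keeps trace >= 0)
    amplitude_scale: float = 0.01    # intensity -> peak height factor


def emit_spectra(cohort: SyntheticCohort, modality: str = "metabolite",
                 spectra_config: SpectraConfig | None = None,
                 seed: int | None = None):
    """Render each (sample, replicate) of one modality as a raw trace.

    Every feature appears as a Gaussian peak centred at its m/z with height
    proportional to its replicate intensity, over additive Gaussian
    baseline noise (rectified to keep the trace non-negative).  Returns a
    list of ``preprocess.Spectrum``.  Feature pairs closer than twice the
    peak width trigger an overlap warning.
    """
    from .preprocess import Spectrum  # local import avoids a cycle

    sc = spectra_config or SpectraConfig()
    if modality == "metabolite":
        lo, hi = sc.met_range
        step, width = sc.met_grid_step, sc.met_peak_width
    elif modality == "peptide":
        lo, hi = sc.pep_range
        step, width = sc.pep_grid_step, sc.pep_peak_width
    else:
        raise ValueError(f"unknown modality {modality!r}")

    cols = cohort.modality_columns(modality)
    mzs = np.array([f.mz for f in cohort.feature_specs if f.modality == modality])
    order = np.argsort(mzs)
    gaps = np.diff(mzs[order])
    if np.any(gaps < 2 * width):
        warnings.warn(
            f"{int((gaps < 2 * width).sum())} {modality} peak pairs closer "
            f"than 2x peak width; they may merge in the trace", stacklevel=2,
        )

    rng = np.random.default_rng(cohort.config.seed + 1 if seed is None else seed)
    grid = np.arange(lo, hi + step / 2, step)
    out = []
    sub = cohort.intensities[cols]
    for (sid, rep), row in sub.iterrows():
        trace = np.maximum(
            sc.baseline_offset + rng.normal(0.0, sc.noise_sd, grid.size), 0.0)
        for mz, inten in zip(mzs, row.to_numpy()):
            lo_i = np.searchsorted(grid, mz - 5 * width)
            hi_i = np.searchsorted(grid, mz + 5 * width)
            window = grid[lo_i:hi_i]
            trace[lo_i:hi_i] += (sc.amplitude_scale * inten
                                 * np.exp(-0.5 * ((window - mz) / width) ** 2))
        out.append(Spectrum(mz=grid.copy(), intensity=trace, sample_id=sid,
                            replicate=int(rep), modality=modality))
    return out
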