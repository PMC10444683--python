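"""Synthetic-study generation for every pipeline input.

The clinical raw data behind the reference tables are not deposited, so
this module generates statistically matched stand-ins: a longitudinal
urine study with the published design (53 patients sampled at 7 time
points with 53/50/10/8/7/3/2 samples, 133 in total, 11 metabolites),
calibration batches, QC batches for the validation battery, and incurred
sample reanalysis pairs.  All outputs are synthetic.

The study generator draws from exactly the hierarchical model the
longitudinal module fits: per-patient correlated metabolite effects, a
per-sample diuresis intercept common to all metabolites of a sample,
per-metabolite residual SDs on the log scale, and fixed time-by-
metabolite fold effects.  Baseline levels default to the published
pre-surgery means; the default fold effects place a 0.5× effect on MTA
and a 1.7× effect on Ino at 24 h, the two signals the study design is
meant to detect, and 1 everywhere else.

Every generator is driven by one integer seed through independent
``SeedSequence`` streams, so tables reproduce bit-identically across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .panel import ANALYTES, panel_by_code
from .quantify import TIME_POINTS
from .reference import load_reference_calibration, load_reference_study_levels

__all__ = [
    "StudyDesign",
    "GenerativeParams",
    "simulate_study",
    "simulate_calibration_batch",
    "simulate_qc_batch",
    "simulate_isr_pairs",
    "DEFAULT_SAMPLE_COUNTS",
]

#: Samples retained per time point in the study design (133 in total).
DEFAULT_SAMPLE_COUNTS = (53, 50, 10, 8, 7, 3, 2)


@dataclass(frozen=True)
class StudyDesign:
    """Who is sampled when: patients, per-time-point counts, panel."""

    n_patients: int = 53
    sample_counts: tuple = DEFAULT_SAMPLE_COUNTS
    metabolites: tuple = ANALYTES

    def __post_init__(self):
        if len(self.sample_counts) != len(TIME_POINTS):
            raise ValueError(f"need one sample count per time point ({len(TIME_POINTS)})")
        if any(c > self.n_patients for c in self.sample_counts):
            raise ValueError("a time point cannot have more samples than patients")

    @property
    def n_samples(self) -> int:
        return int(sum(self.sample_counts))


def _default_baselines(metabolites) -> dict[str, float]:
    ref = load_reference_study_levels().set_index("analyte_code")
    # panel analytes start at the published pre-surgery means; any other
    # code gets a unit baseline (log 1 = 0)
    return {
        m: float(np.log(ref.loc[m, "pre_mean"])) if m in ref.index else 0.0
        for m in metabolites
    }


def _default_folds(metabolites) -> dict[tuple[str, str], float]:
    folds = {}
    if "MTA" in metabolites:
        folds[("MTA", "24h")] = 0.5
    if "Ino" in metabolites:
        folds[("Ino", "24h")] = 1.7
    return folds


@dataclass
class GenerativeParams:
    """Truth parameters of the synthetic study.

    ``baseline_log_mean`` defaults to the log of the published pre-surgery
    mean normalized concentrations so synthetic data land on realistic
    scales.  ``time_folds`` maps (metabolite, time label) to a fold
    multiplier (default 1 except MTA 0.5× and Ino 1.7× at 24 h).  The
    log-scale variance components default to modest values typical of
    urinary metabolite panels: between-patient SD 0.3 with correlation
    0.5 across metabolites, per-sample diuresis SD 0.25, residual SD 0.4.
    Urinary creatinine is log-normal with median 10 mM and 50% CV.
    """

    metabolites: tuple = ANALYTES
    baseline_log_mean: dict = None
    time_folds: dict = None
    id_sd: float = 0.3
    id_corr: float = 0.5
    tau_sample: float = 0.25
    sigma_met: dict = None
    creatinine_median_mM: float = 10.0
    creatinine_cv: float = 0.5

    def __post_init__(self):
        if self.baseline_log_mean is None:
            self.baseline_log_mean = _default_baselines(self.metabolites)
        if self.time_folds is None:
            self.time_folds = _default_folds(self.metabolites)
        if self.sigma_met is None:
            self.sigma_met = {m: 0.4 for m in self.metabolites}
        if any(f <= 0 for f in self.time_folds.values()):
            raise DomainError("fold multipliers must be positive")
        if self.id_sd < 0 or self.tau_sample < 0 or any(s <= 0 for s in self.sigma_met.values()):
            raise DomainError("variance components must be non-negative (residual SDs positive)")

    def sigma_id_matrix(self) -> np.ndarray:
        M = len(self.metabolites)
        corr = np.full((M, M), self.id_corr)
        np.fill_diagonal(corr, 1.0)
        if np.any(np.linalg.eigvalsh(corr) < -1e-10):
            raise DomainError("metabolite correlation matrix is not positive semi-definite")
        return self.id_sd**2 * corr


def simulate_study(
    design: StudyDesign | None = None,
    params: GenerativeParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a longitudinal study table plus its latent truth record.

    Dropout follows the designed counts: the first *k* patients are
    retained at each time point.  Returns a long DataFrame with columns
    ``patient_id, sample_id, time_point, analyte_code, conc_uM,
    creatinine_mM, normalized_ratio, logDV`` and a truth dict holding the
    fixed effects and every latent draw, for recovery tests.
    """
    design = design or StudyDesign()
    params = params or GenerativeParams()
    if tuple(params.metabolites) != tuple(design.metabolites):
        params = GenerativeParams(
            metabolites=design.metabolites,
            baseline_log_mean={m: params.baseline_log_mean[m] for m in design.metabolites
                               if m in params.baseline_log_mean},
            time_folds={k: v for k, v in params.time_folds.items() if k[0] in design.metabolites},
            id_sd=params.id_sd, id_corr=params.id_corr, tau_sample=params.tau_sample,
            sigma_met={m: s for m, s in params.sigma_met.items() if m in design.metabolites},
            creatinine_median_mM=params.creatinine_median_mM,
            creatinine_cv=params.creatinine_cv,
        )
    mets = list(design.metabolites)
    M = len(mets)
    Sigma = params.sigma_id_matrix()

    ss = np.random.SeedSequence(int(seed))
    r_patient, r_sample, r_resid, r_creat = [np.random.default_rng(s) for s in ss.spawn(4)]

    chol = np.linalg.cholesky(Sigma + 1e-12 * np.eye(M)) if params.id_sd > 0 else np.zeros((M, M))
    patient_effects = (chol @ r_patient.standard_normal((M, design.n_patients))).T  # (P, M)

    creat_sigma = np.sqrt(np.log1p(params.creatinine_cv**2))

    rows = []
    truth_samples = {}
    for t_idx, (label, count) in enumerate(zip(TIME_POINTS, design.sample_counts)):
        for p in range(count):
            pid = f"P{p + 1:03d}"
            sid = f"{pid}|{label}"
            u = float(r_sample.normal(0.0, params.tau_sample)) if params.tau_sample > 0 else 0.0
            creat = float(
                params.creatinine_median_mM * np.exp(r_creat.normal(0.0, creat_sigma))
            )
            truth_samples[sid] = u
            for k, met in enumerate(mets):
                logfold = np.log(params.time_folds.get((met, label), 1.0))
                mu = params.baseline_log_mean[met] + logfold + patient_effects[p, k] + u
                eps = float(r_resid.normal(0.0, params.sigma_met[met]))
                logdv = mu + eps
                ratio = float(np.exp(logdv))
                rows.append(
                    {
                        "patient_id": pid,
                        "sample_id": sid,
                        "time_point": label,
                        "analyte_code": met,
                        "conc_uM": ratio * creat,
                        "creatinine_mM": creat,
                        "normalized_ratio": ratio,
                        "logDV": logdv,
                    }
                )
    truth = {
        "metabolites": mets,
        "baseline_log_mean": dict(params.baseline_log_mean),
        "time_folds": dict(params.time_folds),
        "Sigma_ID": Sigma,
        "tau_sample": params.tau_sample,
        "sigma_met": dict(params.sigma_met),
        "patient_effects": patient_effects,
        "sample_intercepts": truth_samples,
        "seed": int(seed),
    }
    return pd.DataFrame(rows), truth


def simulate_calibration_batch(
    analyte: str,
    n_levels: int = 8,
    replicates: int = 1,
    noise_cv: float = 0.02,
    is_area: float = 1.0e5,
    is_cv: float = 0.0,
    seed: int = 0,
    slope: float | None = None,
    intercept: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a calibration peak table and nominal table for one analyte.

    Truth defaults to the published slope/intercept and linear range; the
    eight levels are geometrically spaced over that range.  Noise is
    heteroscedastic to match the analyte's published weighting scheme: SD
    proportional to the response for 1/y analytes, proportional to the
    square root of concentration for 1/x analytes, so the printed
    weighting is approximately the optimal choice.  Qualifier areas are
    generated at the panel's expected ion ratio.
    """
    ref = load_reference_calibration().set_index("analyte_code")
    if analyte not in ref.index:
        raise ValueError(f"unknown analyte {analyte!r}")
    row = ref.loc[analyte]
    slope = float(row["slope"]) if slope is None else slope
    intercept = float(row["intercept"]) if intercept is None else intercept
    if not slope > 0:
        raise DomainError("calibration truth slope must be positive")
    weighting = str(row["weighting"]).replace("1/y", "1/y").replace("1/x", "1/x")
    levels = np.geomspace(float(row["range_low_uM"]), float(row["range_high_uM"]), n_levels)
    spec = panel_by_code().get(analyte)
    ratio = spec.expected_ion_ratio_pct / 100.0 if spec and spec.has_ion_ratio_window else 0.2

    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    peaks, nominals = [], []
    for i, conc in enumerate(levels):
        for rep in range(replicates):
            mean_resp = slope * conc + intercept
            if noise_cv > 0:
                if weighting == "1/x":
                    sd = noise_cv * slope * np.sqrt(conc * levels.max())
                else:  # 1/y (and unweighted): proportional to signal
                    sd = noise_cv * mean_resp
                resp = mean_resp + rng.normal(0.0, sd)
            else:
                resp = mean_resp
            isa = is_area * (1.0 + (rng.normal(0.0, is_cv) if is_cv > 0 else 0.0))
            sid = f"CAL{i + 1:02d}R{rep + 1}"
            peaks.append(
                {
                    "sample_id": sid,
                    "analyte_code": analyte,
                    "quantifier_area": resp * isa,
                    "qualifier_area": resp * isa * ratio,
                    "is_area": isa,
                }
            )
            nominals.append({"sample_id": sid, "analyte_code": analyte, "nominal_uM": conc})
    return pd.DataFrame(peaks), pd.DataFrame(nominals)


def simulate_qc_batch(
    nominals: dict[str, float] | None = None,
    n_runs: int = 4,
    replicates: int = 6,
    run_bias_cv: float = 0.03,
    replicate_cv: float = 0.05,
    analyte: str = "Ino",
    seed: int = 0,
) -> pd.DataFrame:
    """Generate measured QC concentrations grouped by level and run.

    ``measured = nominal × (1 + run bias + replicate noise)`` with the
    run bias shared within a run, so expected accuracy is 100% and the
    expected within-run CV equals ``replicate_cv``.  Levels default to
    the analyte's published QC ladder (LLOQ/LQC/MQC/HQC).
    """
    if nominals is None:
        from .reference import load_reference_qc_performance

        qc = load_reference_qc_performance()
        sub = qc[qc["analyte_code"] == analyte]
        nominals = dict(zip(sub["level"], sub["nominal_uM"].astype(float)))
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    rows = []
    for level, nominal in nominals.items():
        for run in range(1, n_runs + 1):
            bias = rng.normal(0.0, run_bias_cv) if run_bias_cv > 0 else 0.0
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, replicate_cv) if replicate_cv > 0 else 0.0
                rows.append(
                    {
                        "analyte_code": analyte,
                        "level": level,
                        "nominal_uM": nominal,
                        "run": run,
                        "replicate": rep,
                        "conc_uM": nominal * (1.0 + bias + noise),
                    }
                )
    return pd.DataFrame(rows)


def simulate_isr_pairs(
    n_pairs: int = 15,
    true_cv: float = 0.05,
    outlier_fraction: float = 0.0,
    outlier_scale: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate incurred-sample-reanalysis pairs.

    Each pair shares a log-normal truth with independent measurement
    noise of CV ``true_cv``; a ``outlier_fraction`` of repeats is
    multiplied by ``outlier_scale`` to push the pair past the 20% rule.
    """
    if not 0.0 <= outlier_fraction <= 1.0:
        raise DomainError("outlier fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    truths = np.exp(rng.normal(0.0, 0.5, n_pairs))
    initial = truths * (1.0 + rng.normal(0.0, true_cv, n_pairs))
    repeat = truths * (1.0 + rng.normal(0.0, true_cv, n_pairs))
    n_out = int(round(outlier_fraction * n_pairs))
    if n_out:
        idx = rng.choice(n_pairs, size=n_out, replace=False)
        repeat[idx] *= outlier_scale
    return pd.DataFrame(
        {
            "sample_id": [f"ISR{i + 1:02d}" for i in range(n_pairs)],
            "initial_uM": initial,
            "repeat_uM": repeat,
        }
    )
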