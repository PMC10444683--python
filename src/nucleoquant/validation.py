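"""The bioanalytical validation battery with EMA/FDA pass rules.

Covers accuracy, precision, matrix effect, recovery, stability,
quantifier/qualifier ion-ratio purity, selectivity, and incurred sample
reanalysis (ISR).  Every pass/fail flag is a pure function of its stated
threshold, and every threshold interval is closed: a value exactly on the
boundary passes.

Thresholds:

* accuracy within 15% of nominal (20% at the LLOQ level);
* precision CV at most 15% (20% at LLOQ);
* matrix effect: CV of internal-standard-normalized matrix factors at
  most 15%;
* stability: mean within ±15% of nominal;
* ISR: percent difference (mean-denominator form) at most 20% in at
  least two-thirds of the repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, InsufficientDataError
from .panel import TransitionRecord
from .utils import round_half_up

__all__ = [
    "accuracy_pct",
    "precision_cv",
    "assess_accuracy_precision",
    "AccuracyPrecisionResult",
    "matrix_effect_cv",
    "MatrixEffectResult",
    "recovery_pct",
    "stability_assess",
    "StabilityResult",
    "ion_ratio_check",
    "IonRatioCheck",
    "selectivity_check",
    "isr_percent_difference",
    "isr_evaluate",
    "IsrResult",
    "summarize_ranges",
]

QC_LEVELS = ("LLOQ", "LQC", "MQC", "HQC")

ACCURACY_TOL_PCT = 15.0
ACCURACY_TOL_LLOQ_PCT = 20.0
PRECISION_TOL_PCT = 15.0
PRECISION_TOL_LLOQ_PCT = 20.0
MATRIX_EFFECT_TOL_PCT = 15.0
STABILITY_TOL_PCT = 15.0
ISR_DIFF_TOL_PCT = 20.0
ISR_PASS_FRACTION = 2.0 / 3.0


# ---------------------------------------------------------------------------
# accuracy / precision


def accuracy_pct(measured, nominal: float) -> float:
    """Mean measured concentration as a percentage of nominal."""
    m = np.asarray(measured, dtype=float)
    if m.size == 0:
        raise InsufficientDataError("accuracy needs at least one measurement")
    if not nominal > 0:
        raise DomainError("nominal concentration must be positive")
    return 100.0 * float(m.mean()) / nominal


def precision_cv(measured) -> float:
    """Coefficient of variation (%), sample SD (n-1) over the mean."""
    m = np.asarray(measured, dtype=float)
    if m.size < 2:
        raise InsufficientDataError("precision needs at least two measurements")
    mean = m.mean()
    if mean == 0:
        raise DomainError("cannot compute a CV around a zero mean")
    return 100.0 * float(m.std(ddof=1)) / float(mean)


@dataclass(frozen=True)
class AccuracyPrecisionResult:
    analyte_code: str
    level: str
    scope: str  # "within_run" or "between_run"
    nominal_uM: float
    accuracy_pct: float
    cv_pct: float
    n: int
    pass_accuracy: bool
    pass_precision: bool


def _tolerances(level: str) -> tuple[float, float]:
    if level == "LLOQ":
        return ACCURACY_TOL_LLOQ_PCT, PRECISION_TOL_LLOQ_PCT
    return ACCURACY_TOL_PCT, PRECISION_TOL_PCT


def assess_accuracy_precision(qc_runs: pd.DataFrame) -> list[AccuracyPrecisionResult]:
    """Evaluate QC accuracy and precision within and between runs.

    ``qc_runs`` is a long table with columns ``analyte_code, level,
    nominal_uM, run, conc_uM``.  Within-run statistics use each run's
    replicates separately (reported per the first run); between-run
    statistics pool the replicates of all runs.  Cells with insufficient
    replication are omitted rather than failed.
    """
    required = {"analyte_code", "level", "nominal_uM", "run", "conc_uM"}
    missing = required - set(qc_runs.columns)
    if missing:
        raise ValueError(f"qc_runs is missing columns: {sorted(missing)}")
    out: list[AccuracyPrecisionResult] = []
    for (analyte, level), cell in qc_runs.groupby(["analyte_code", "level"], sort=False):
        nominal = float(cell["nominal_uM"].iloc[0])
        acc_tol, cv_tol = _tolerances(level)
        first_run = cell[cell["run"] == cell["run"].iloc[0]]
        if len(first_run) >= 2:
            acc = accuracy_pct(first_run["conc_uM"], nominal)
            cv = precision_cv(first_run["conc_uM"])
            out.append(
                AccuracyPrecisionResult(
                    analyte, level, "within_run", nominal, acc, cv, len(first_run),
                    pass_accuracy=abs(acc - 100.0) <= acc_tol,
                    pass_precision=cv <= cv_tol,
                )
            )
        if cell["run"].nunique() >= 2:
            acc = accuracy_pct(cell["conc_uM"], nominal)
            cv = precision_cv(cell["conc_uM"])
            out.append(
                AccuracyPrecisionResult(
                    analyte, level, "between_run", nominal, acc, cv, len(cell),
                    pass_accuracy=abs(acc - 100.0) <= acc_tol,
                    pass_precision=cv <= cv_tol,
                )
            )
    return out


# ---------------------------------------------------------------------------
# matrix effect


@dataclass(frozen=True)
class MatrixEffectResult:
    analyte_code: str
    level: str
    mf_analyte: tuple
    mf_is: tuple
    normalized_mf: tuple
    me_cv_pct: float
    passed: bool


def matrix_effect_cv(
    areas_with_matrix,
    areas_without_matrix,
    is_with,
    is_without,
    analyte_code: str = "",
    level: str = "",
) -> MatrixEffectResult:
    """Matrix effect as the CV of internal-standard-normalized matrix factors.

    For each replicate, the matrix factor (MF) is the peak area in the
    presence of the matrix divided by the area without matrix; the analyte
    MF is normalized by the internal standard's MF, and the matrix effect
    is ``100 × SD / mean`` of those normalized factors.  Passes at CV ≤ 15%.
    """
    aw = np.asarray(areas_with_matrix, dtype=float)
    ao = np.asarray(areas_without_matrix, dtype=float)
    iw = np.asarray(is_with, dtype=float)
    io = np.asarray(is_without, dtype=float)
    if not (aw.size == ao.size == iw.size == io.size):
        raise ValueError("matrix-effect replicate groups must be paired (equal counts)")
    if aw.size < 3:
        raise InsufficientDataError("matrix effect needs at least 3 paired replicates")
    if np.any(np.concatenate([aw, ao, iw, io]) <= 0):
        raise DomainError("all peak areas must be positive")
    mf_a = aw / ao
    mf_is = iw / io
    norm = mf_a / mf_is
    cv = 100.0 * float(norm.std(ddof=1)) / float(norm.mean())
    return MatrixEffectResult(
        analyte_code=analyte_code,
        level=level,
        mf_analyte=tuple(mf_a),
        mf_is=tuple(mf_is),
        normalized_mf=tuple(norm),
        me_cv_pct=cv,
        passed=cv <= MATRIX_EFFECT_TOL_PCT,
    )


# ---------------------------------------------------------------------------
# recovery


def recovery_pct(extracted_responses, postspiked_responses) -> float:
    """Extraction recovery: mean extracted response over mean post-spiked response, %."""
    e = np.asarray(extracted_responses, dtype=float)
    p = np.asarray(postspiked_responses, dtype=float)
    if e.size == 0 or p.size == 0:
        raise InsufficientDataError("recovery needs both replicate groups")
    if not p.mean() > 0:
        raise DomainError("post-spiked mean response must be positive")
    return 100.0 * float(e.mean()) / float(p.mean())


# ---------------------------------------------------------------------------
# stability


@dataclass(frozen=True)
class StabilityResult:
    analyte_code: str
    condition: str  # bench_top, autosampler, freeze_thaw
    label: str  # time point or cycle
    level: str
    pct_of_nominal: float
    passed: bool


def stability_assess(
    measured_mean: float,
    nominal: float,
    condition: str,
    label: str,
    level: str,
    analyte_code: str = "",
) -> StabilityResult:
    """Stability as percent of nominal; passes inside the closed ±15% window."""
    if not nominal > 0:
        raise DomainError("nominal concentration must be positive")
    pct = 100.0 * measured_mean / nominal
    ok = (100.0 - STABILITY_TOL_PCT) <= pct <= (100.0 + STABILITY_TOL_PCT)
    return StabilityResult(analyte_code, condition, label, level, pct, ok)


# ---------------------------------------------------------------------------
# ion-ratio purity and selectivity


@dataclass(frozen=True)
class IonRatioCheck:
    analyte_code: str
    observed_ratio_pct: float
    low_pct: float
    high_pct: float
    passed: bool


def ion_ratio_check(
    qualifier_area: float, quantifier_area: float, spec: TransitionRecord
) -> IonRatioCheck:
    """Peak-purity check: qualifier/quantifier area ratio inside the panel window.

    The per-analyte printed uncertainty range is the operative window;
    when a panel entry lacks one, a default ±20% band around the expected
    ratio applies.  The window is closed at both ends.
    """
    if not quantifier_area > 0:
        raise DomainError("quantifier area must be positive")
    observed = 100.0 * qualifier_area / quantifier_area
    if np.isfinite(spec.ion_ratio_low_pct) and np.isfinite(spec.ion_ratio_high_pct):
        low, high = spec.ion_ratio_low_pct, spec.ion_ratio_high_pct
    else:
        low = 0.8 * spec.expected_ion_ratio_pct
        high = 1.2 * spec.expected_ion_ratio_pct
    return IonRatioCheck(
        analyte_code=spec.analyte_code,
        observed_ratio_pct=observed,
        low_pct=low,
        high_pct=high,
        passed=low <= observed <= high,
    )


def selectivity_check(blank_response: float, lloq_response: float, tol_fraction: float = 0.2) -> bool:
    """Blank interference screen at the analyte's retention window.

    Passes when the blank signal is at most ``tol_fraction`` (default 20%)
    of the LLOQ response.
    """
    if not lloq_response > 0:
        raise DomainError("LLOQ response must be positive")
    return blank_response <= tol_fraction * lloq_response


# ---------------------------------------------------------------------------
# incurred sample reanalysis


def isr_percent_difference(initial: float, repeat: float, signed: bool = False) -> float:
    """ISR percent difference with the guideline's mean denominator.

    ``100 × (repeat − initial) / mean(initial, repeat)``; the absolute
    value is returned unless ``signed=True``.
    """
    mean = 0.5 * (initial + repeat)
    if mean <= 0:
        raise DomainError("ISR needs a positive mean concentration")
    diff = 100.0 * (repeat - initial) / mean
    return diff if signed else abs(diff)


@dataclass(frozen=True)
class IsrResult:
    pct_differences: tuple
    within_tol_fraction: float
    passed: bool
    max_difference_pct: float
    n_exceeding: int
    labels: tuple = field(default_factory=tuple)


def isr_evaluate(pairs=None, differences=None, labels=None) -> IsrResult:
    """Evaluate incurred sample reanalysis over pairs or precomputed differences.

    Either ``pairs`` (iterable of (initial, repeat) concentrations) or
    ``differences`` (percent differences, e.g. a published difference
    matrix flattened) must be given.  Passing requires the difference to
    be at most 20% (closed) in at least two-thirds of the entries; the
    summary also reports the maximum difference and the count exceeding
    20%, since strictness conventions vary at the margin.
    """
    if (pairs is None) == (differences is None):
        raise ValueError("provide exactly one of pairs or differences")
    if pairs is not None:
        diffs = np.array([isr_percent_difference(a, b) for a, b in pairs], dtype=float)
    else:
        diffs = np.asarray(differences, dtype=float).ravel()
    if diffs.size == 0:
        raise InsufficientDataError("ISR needs at least one pair")
    within = diffs <= ISR_DIFF_TOL_PCT
    frac = float(within.mean())
    return IsrResult(
        pct_differences=tuple(diffs),
        within_tol_fraction=frac,
        passed=frac >= ISR_PASS_FRACTION,
        max_difference_pct=float(diffs.max()),
        n_exceeding=int((~within).sum()),
        labels=tuple(labels) if labels is not None else (),
    )


# ---------------------------------------------------------------------------
# report summarization


def summarize_ranges(values, exclude_mask=None, ndigits: int = 1) -> tuple[float, float]:
    """(min, max) of a metric column, half-up rounded to ``ndigits`` decimals.

    ``exclude_mask`` removes entries (e.g. an analyte excluded from the
    headline range) before the scan.
    """
    v = np.asarray(values, dtype=float)
    if exclude_mask is not None:
        v = v[~np.asarray(exclude_mask, dtype=bool)]
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise InsufficientDataError("no values left to summarize")
    return round_half_up(float(v.min()), ndigits), round_half_up(float(v.max()), ndigits)
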