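"""Loaders for the packaged reference validation dataset.

These tables are the published method-characterization values for the
11-analyte urinary nucleoside panel: calibration parameters (slope,
intercept, their SDs and 95% CIs, correlation, residual SD, LOD/LOQ),
the accuracy/precision/recovery/matrix-effect summary, the stability
battery, per-time-point study concentration summaries, and the incurred
sample reanalysis percent-difference matrix.  They serve as regression
fixtures for the pipeline's report summarizers and formula checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_reference_calibration",
    "load_reference_qc_performance",
    "load_reference_stability",
    "load_reference_study_levels",
    "load_reference_isr_differences",
]


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("nucleoquant.data").joinpath(name)) as p:
        return pd.read_csv(p)


def load_reference_calibration() -> pd.DataFrame:
    """Calibration-curve parameters per analyte, concentrations in µM.

    The ``intercept_ci_duplicates_slope_ci`` flag marks the one analyte
    (2dG) whose printed intercept confidence interval duplicates the slope
    interval; the values are stored as printed.
    """
    return _read("reference_calibration.csv")


def load_reference_qc_performance() -> pd.DataFrame:
    """Accuracy, precision (CV), recovery and matrix-effect CV per analyte × QC level."""
    return _read("reference_qc_performance.csv")


def load_reference_stability() -> pd.DataFrame:
    """Stability results (percent of nominal) per analyte × level × condition × label."""
    return _read("reference_stability.csv")


def load_reference_study_levels() -> pd.DataFrame:
    """Creatinine-normalized concentration summaries per analyte × time point.

    Means and SDs for the first six time points; min/max for the 12-month
    point, where only two samples were collected.  ``alt_units_flag`` marks
    analytes whose printed values carry the alternate (nano-scale) unit
    footnote; the ambiguity in that footnote's denominator unit is left as
    printed and the package core works in µM/mM throughout.
    """
    return _read("reference_study_levels.csv")


def load_reference_isr_differences() -> pd.DataFrame:
    """Incurred-sample-reanalysis percent differences, 15 samples × 11 analytes."""
    return _read("reference_isr_differences.csv").set_index("sample_id")
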