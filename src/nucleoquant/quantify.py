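"""Study-sample quantification and creatinine normalization.

Turns MRM peak tables for study samples into creatinine-normalized
concentrations (µmol analyte per mmol creatinine) using fitted
calibration curves.  Results below the quantification limits or with an
ion ratio outside the panel window are flagged, never dropped: the
downstream longitudinal model decides how to handle them.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calibration import CalibrationCurve, back_calculate
from .exceptions import ConfigurationError, DomainError
from .io import PeakRecord, SampleMeta
from .panel import TransitionRecord
from .validation import ion_ratio_check

__all__ = ["LongitudinalRecord", "quantify_samples", "creatinine_normalize", "records_to_frame"]

TIME_POINTS = ("pre", "24h", "2wk", "3mo", "6mo", "9mo", "12mo")


@dataclass(frozen=True)
class LongitudinalRecord:
    """One creatinine-normalized measurement for (patient, time, analyte)."""

    patient_id: str
    time_point_label: str
    analyte_code: str
    conc_uM: float
    creatinine_mM: float
    normalized_ratio: float  # µmol analyte / mmol creatinine
    flags: frozenset


def creatinine_normalize(conc_uM: float, creatinine_mM: float) -> float:
    """Concentration per millimole of creatinine (µmol/mmol).

    Dividing by urinary creatinine corrects for between-sample differences
    in urine dilution (diuresis).
    """
    if not creatinine_mM > 0:
        raise DomainError("creatinine concentration must be positive")
    return conc_uM / creatinine_mM


def quantify_samples(
    peaks: list[PeakRecord],
    meta: list[SampleMeta],
    curves: dict[str, CalibrationCurve],
    panel: dict[str, TransitionRecord],
) -> list[LongitudinalRecord]:
    """Quantify every study-sample peak against its analyte's calibration curve.

    The relative response (quantifier area / IS area) is back-calculated
    through the curve, the qualifier/quantifier ratio is screened against
    the panel window, and the concentration is creatinine-normalized.
    Rows for blank/calibration/QC samples are excluded; one output record
    is produced per (study sample × analyte) peak row.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    records: list[LongitudinalRecord] = []
    for peak in peaks:
        sample = meta_by_id.get(peak.sample_id)
        if sample is None or sample.role != "study":
            continue
        curve = curves.get(peak.analyte_code)
        if curve is None:
            raise ConfigurationError(f"no calibration curve fitted for {peak.analyte_code!r}")
        bc = back_calculate(peak.relative_response, curve)
        flags = set(bc.flags)
        spec = panel.get(peak.analyte_code)
        if spec is not None and spec.has_ion_ratio_window:
            if not ion_ratio_check(peak.qualifier_area, peak.quantifier_area, spec).passed:
                flags.add("ion_ratio_fail")
        records.append(
            LongitudinalRecord(
                patient_id=sample.patient_id,
                time_point_label=sample.time_point_label,
                analyte_code=peak.analyte_code,
                conc_uM=bc.conc_uM,
                creatinine_mM=sample.creatinine_mM,
                normalized_ratio=creatinine_normalize(bc.conc_uM, sample.creatinine_mM),
                flags=frozenset(flags),
            )
        )
    return records


def records_to_frame(records: list[LongitudinalRecord]) -> pd.DataFrame:
    """Long-format DataFrame view of quantified records."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_point": [r.time_point_label for r in records],
            "analyte_code": [r.analyte_code for r in records],
            "conc_uM": [r.conc_uM for r in records],
            "creatinine_mM": [r.creatinine_mM for r in records],
            "normalized_ratio": [r.normalized_ratio for r in records],
            "flags": ["|".join(sorted(r.flags)) for r in records],
        }
    )
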