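"""Readers and writers for the delimited tables the pipeline exchanges.

Every interchange format is delimited text with an explicit header
(delimiter configurable, comma by default) because vendor peak-table
exports vary.  Writers store floats with 17 significant digits so that a
write/read round trip reproduces values bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import SchemaError, TableParseError

__all__ = [
    "PeakRecord",
    "SampleMeta",
    "read_peak_table",
    "read_sample_meta",
    "read_nominal_table",
    "read_longitudinal_table",
    "write_table",
    "read_table",
]

PEAK_COLUMNS = ("sample_id", "analyte_code", "quantifier_area", "qualifier_area", "is_area")
LONGITUDINAL_COLUMNS = ("patient_id", "time_point", "analyte_code", "conc_uM", "creatinine_mM")

SAMPLE_ROLES = ("blank", "calibration", "qc", "study")


@dataclass(frozen=True)
class PeakRecord:
    """Integrated areas for one (sample, analyte) pair.

    ``is_area`` is the internal-standard (8BrG) area in the same injection;
    it must be positive whenever a relative response is computed.
    """

    sample_id: str
    analyte_code: str
    quantifier_area: float
    qualifier_area: float
    is_area: float

    @property
    def relative_response(self) -> float:
        """Quantifier area normalized by the internal-standard area."""
        if not self.is_area > 0:
            raise ValueError(
                f"sample {self.sample_id}/{self.analyte_code}: "
                "internal-standard area must be positive for a relative response"
            )
        return self.quantifier_area / self.is_area


@dataclass(frozen=True)
class SampleMeta:
    """Role and role-conditional metadata for one sample.

    Calibration/QC samples carry nominal concentrations per analyte; study
    samples carry patient id, time-point label and creatinine.
    """

    sample_id: str
    role: str
    nominal_concentrations: dict[str, float] = field(default_factory=dict)
    patient_id: str | None = None
    time_point_label: str | None = None
    creatinine_mM: float | None = None

    def __post_init__(self):
        if self.role not in SAMPLE_ROLES:
            raise ValueError(f"unknown sample role {self.role!r}")
        if self.role in ("calibration", "qc") and not self.nominal_concentrations:
            raise ValueError(f"sample {self.sample_id}: {self.role} samples need nominal concentrations")
        if self.role == "study":
            if self.patient_id is None or self.time_point_label is None:
                raise ValueError(f"sample {self.sample_id}: study samples need patient id and time point")
            if self.creatinine_mM is None:
                raise ValueError(f"sample {self.sample_id}: study samples need a creatinine concentration")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise TableParseError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {row}",
                row=row,
            )
        df[col] = parsed
    return df


def read_peak_table(path, delimiter: str = ",") -> list[PeakRecord]:
    """Read an MRM peak-area table into :class:`PeakRecord` rows.

    The file must name the columns ``sample_id, analyte_code,
    quantifier_area, qualifier_area, is_area``; numeric fields accept any
    standard notation (including scientific).  Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    _require_columns(df, PEAK_COLUMNS, path)
    df = _parse_numeric(df, ("quantifier_area", "qualifier_area", "is_area"), path)
    return [
        PeakRecord(
            sample_id=str(r.sample_id),
            analyte_code=str(r.analyte_code),
            quantifier_area=float(r.quantifier_area),
            qualifier_area=float(r.qualifier_area),
            is_area=float(r.is_area),
        )
        for r in df.itertuples(index=False)
    ]


def read_sample_meta(path, delimiter: str = ",") -> list[SampleMeta]:
    """Read a sample-metadata table.

    Expected columns: ``sample_id, role`` plus, for study samples,
    ``patient_id, time_point, creatinine_mM``.  Nominal concentrations for
    calibration/QC samples live in a separate long-format nominal table
    (see :func:`read_nominal_table`) keyed by sample id; pass its output as
    ``nominals`` to :func:`attach_nominals` or merge manually.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    _require_columns(df, ("sample_id", "role"), path)
    if "creatinine_mM" in df.columns:
        df = _parse_numeric(df, ("creatinine_mM",), path)
    metas = []
    for r in df.itertuples(index=False):
        role = str(r.role)
        metas.append(
            SampleMeta(
                sample_id=str(r.sample_id),
                role=role,
                # nominal concentrations are attached from the nominal table
                nominal_concentrations={"__pending__": 0.0} if role in ("calibration", "qc") else {},
                patient_id=str(r.patient_id) if role == "study" else None,
                time_point_label=str(r.time_point) if role == "study" else None,
                creatinine_mM=float(r.creatinine_mM) if role == "study" else None,
            )
        )
    return metas


def read_nominal_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a long-format nominal-concentration table.

    Columns: ``sample_id, analyte_code, nominal_uM``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    _require_columns(df, ("sample_id", "analyte_code", "nominal_uM"), path)
    return _parse_numeric(df, ("nominal_uM",), path)


def read_longitudinal_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a longitudinal concentration table.

    Columns: ``patient_id, time_point, analyte_code, conc_uM,
    creatinine_mM`` (an optional ``normalized_ratio`` column is parsed when
    present).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    _require_columns(df, LONGITUDINAL_COLUMNS, path)
    numeric = ["conc_uM", "creatinine_mM"]
    if "normalized_ratio" in df.columns:
        numeric.append("normalized_ratio")
    return _parse_numeric(df, numeric, path)


def write_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a result table as delimited text at full double precision.

    Floats are rendered with ``repr`` precision (17 significant digits) so
    a round trip through :func:`read_table` restores them bit-identically.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(Path(path), sep=delimiter, float_precision="round_trip")
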