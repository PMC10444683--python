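"""The 11-analyte urinary nucleoside/deoxynucleoside MRM panel.

Each analyte is monitored by two product-ion transitions in dynamic-MRM
mode: a quantifier (used for quantitation, after normalization to the
internal standard 8-bromoguanosine) and a qualifier whose area ratio to the
quantifier confirms peak identity.  The reference panel shipped with the
package carries the transition identities, instrument voltages, retention
times, and the per-analyte ion-ratio acceptance windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "TransitionRecord",
    "ANALYTES",
    "INTERNAL_STANDARD",
    "load_reference_panel",
]

#: Machine-facing analyte codes of the 11-analyte panel (the display name of
#: ``22dmG`` is "2,2dmG"; the comma is dropped to avoid delimiter collision).
ANALYTES = ("Pse", "U", "Ino", "3mU", "2dG", "2mG", "8OH2dG", "6mA", "22dmG", "5-MTA", "MTA")

#: Internal standard code (8-bromoguanosine), spiked into every sample.
INTERNAL_STANDARD = "8BrG"


@dataclass(frozen=True)
class TransitionRecord:
    """One compound's dynamic-MRM identity and ion-ratio window.

    Ion-ratio fields are NaN for the internal standard, which has no
    qualifier acceptance window of its own.
    """

    analyte_code: str
    display_name: str
    retention_time_min: float
    precursor_mz: float
    quantifier_mz: float
    qualifier_mz: float
    ce_quant_v: float
    ce_qual_v: float
    fragmentor_v: float
    expected_ion_ratio_pct: float
    ion_ratio_low_pct: float
    ion_ratio_high_pct: float

    def __post_init__(self):
        if not self.retention_time_min > 0:
            raise ValueError(f"{self.analyte_code}: retention time must be positive")
        if self.quantifier_mz == self.qualifier_mz:
            raise ValueError(f"{self.analyte_code}: quantifier and qualifier m/z must differ")
        if not math.isnan(self.expected_ion_ratio_pct):
            if not (self.ion_ratio_low_pct <= self.expected_ion_ratio_pct <= self.ion_ratio_high_pct):
                raise ValueError(
                    f"{self.analyte_code}: expected ion ratio outside its uncertainty range"
                )

    @property
    def has_ion_ratio_window(self) -> bool:
        return not math.isnan(self.expected_ion_ratio_pct)


def _data_path(name: str):
    return resources.files("nucleoquant.data").joinpath(name)


def load_reference_panel() -> list[TransitionRecord]:
    """Load the packaged reference transition panel.

    Returns 12 records: the 11 analytes plus the internal standard 8BrG.
    """
    with resources.as_file(_data_path("reference_transitions.csv")) as p:
        df = pd.read_csv(p)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TransitionRecord(
                analyte_code=row.analyte_code,
                display_name=row.display_name,
                retention_time_min=float(row.retention_time_min),
                precursor_mz=float(row.precursor_mz),
                quantifier_mz=float(row.quantifier_mz),
                qualifier_mz=float(row.qualifier_mz),
                ce_quant_v=float(row.ce_quant_v),
                ce_qual_v=float(row.ce_qual_v),
                fragmentor_v=float(row.fragmentor_v),
                expected_ion_ratio_pct=float(row.expected_ion_ratio_pct),
                ion_ratio_low_pct=float(row.ion_ratio_low_pct),
                ion_ratio_high_pct=float(row.ion_ratio_high_pct),
            )
        )
    return records


def panel_by_code(panel: list[TransitionRecord] | None = None) -> dict[str, TransitionRecord]:
    """Index a panel (default: the reference panel) by analyte code."""
    if panel is None:
        panel = load_reference_panel()
    return {t.analyte_code: t for t in panel}
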