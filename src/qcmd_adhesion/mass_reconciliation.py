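"""Microscopy-derived areal bacterial mass versus the Sauerbrey prediction.

Counting cells in micrographs gives an areal number density; multiplying by
a per-cell wet mass converts it to an observed areal mass.  The Sauerbrey
relation converts the equilibrium frequency shift at the lowest measured
overtone (n = 3) into the areal mass a thin rigid film would need to
produce that shift.  Comparing the two exposes how badly rigid-film mass
loading describes adhering bacteria: thick soft cell layers, extracellular
polymeric substances and trapped interfacial water make the microscopy mass
far exceed the acoustic prediction, and surfaces with positive frequency
shifts (elastic loading) cannot be assigned a Sauerbrey mass at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .acoustic_models import sauerbrey_areal_mass
from .errors import LabelMismatchError
from .qcm_io import SensorParams
from .trace_analysis import OvertoneShiftSet

__all__ = [
    "CellDensityRecord",
    "cells_to_areal_mass",
    "build_mass_comparison",
    "read_density_table",
    "write_density_table",
    "SAUERBREY_OVERTONE",
    "ELASTIC_FLAG_REASON",
]

#: overtone used for the acoustic mass prediction
SAUERBREY_OVERTONE = 3

ELASTIC_FLAG_REASON = "elastic loading - Sauerbrey inapplicable"

#: cells/mm^2 * pg/cell -> ng/cm^2
_PG_MM2_TO_NG_CM2 = 0.1


@dataclass(frozen=True)
class CellDensityRecord:
    """Cell count summary of one surface from optical micrographs."""

    surface_label: str
    density: float  # cells/mm^2
    density_sd: float = 0.0
    n_fields: int = 1

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.density_sd < 0:
            raise ValueError("density_sd must be >= 0")
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")


def cells_to_areal_mass(record: CellDensityRecord, m_cell: float) -> float:
    """Areal mass (ng/cm^2) from a cell density and per-cell mass (pg)."""
    if not m_cell > 0:
        raise ValueError("per-cell mass must be positive")
    return record.density * m_cell * _PG_MM2_TO_NG_CM2


def build_mass_comparison(
    densities: list[CellDensityRecord],
    shift_sets: dict[str, OvertoneShiftSet],
    sensor: SensorParams | None = None,
    m_cell: float = 1.0,
) -> pd.DataFrame:
    """Join microscopy masses with Sauerbrey predictions per surface.

    Rows with a positive equilibrium shift at n = 3 carry an undefined
    (NaN) prediction and the flag reason instead of a negative mass.  The
    ratio column observed/predicted is NaN wherever the prediction is
    undefined or zero.  Surface labels present in only one input raise
    :class:`LabelMismatchError`.
    """
    sensor = sensor or SensorParams()
    labels = [r.surface_label for r in densities]
    unmatched = sorted(
        set(labels).symmetric_difference(shift_sets.keys())
    )
    if unmatched:
        raise LabelMismatchError(
            f"surface labels not present in both inputs: {unmatched}",
            unmatched=unmatched,
        )

    rows = []
    for rec in densities:
        shifts = shift_sets[rec.surface_label]
        df3 = float(shifts.df_eq[shifts.overtone_index(SAUERBREY_OVERTONE)])
        observed = cells_to_areal_mass(rec, m_cell)
        if df3 > 0:
            predicted, reason = np.nan, ELASTIC_FLAG_REASON
        else:
            predicted, reason = sauerbrey_areal_mass(df3, SAUERBREY_OVERTONE, sensor), ""
        ratio = observed / predicted if predicted and predicted > 0 else np.nan
        rows.append(
            {
                "surface_label": rec.surface_label,
                "density_cells_per_mm2": rec.density,
                "observed_mass_ng_cm2": observed,
                "df_eq3_hz": df3,
                "predicted_mass_ng_cm2": predicted,
                "flag": reason,
                "ratio_observed_predicted": ratio,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "surface_label",
            "density_cells_per_mm2",
            "observed_mass_ng_cm2",
            "df_eq3_hz",
            "predicted_mass_ng_cm2",
            "flag",
            "ratio_observed_predicted",
        ],
    )


def read_density_table(path) -> list[CellDensityRecord]:
    """Read a delimited density table.

    Expected columns: surface_label, density_cells_per_mm2, sd, n_fields.
    """
    table = pd.read_csv(path, comment="#")
    records = []
    for _, row in table.iterrows():
        records.append(
            CellDensityRecord(
                surface_label=str(row["surface_label"]),
                density=float(row["density_cells_per_mm2"]),
                density_sd=float(row.get("sd", 0.0)),
                n_fields=int(row.get("n_fields", 1)),
            )
        )
    return records


def write_density_table(records: list[CellDensityRecord], path) -> None:
    table = pd.DataFrame(
        {
            "surface_label": [r.surface_label for r in records],
            "density_cells_per_mm2": [r.density for r in records],
            "sd": [r.density_sd for r in records],
            "n_fields": [r.n_fields for r in records],
        }
    )
    table.to_csv(Path(path), index=False)
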