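"""Static and dynamic bone histomorphometry from measurement tables.

Dynamic indices follow the standard double-fluorochrome-label scheme:
two calcein doses a known interval apart (7 days here) deposit two
fluorescent fronts on actively mineralizing surfaces.

    MAR    = mean interlabel distance / label interval      [um/day]
    MS/BS  = (dL + 0.5 * sL) / BS                           [fraction]
    BFR/BS = MAR * MS/BS                                    [um^3/um^2/day]

where dL and sL are double- and single-labeled surface lengths and BS is
the total bone surface in the field.  Cell densities are counts per bone
perimeter; osteoclasts must be multinucleated (>= 3 nuclei) to count.

Inputs are measurement tables, not micrographs — label detection on
images is a manual/upstream step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, UndefinedMetricError

#: Days between the two calcein doses in the standard protocol.
DEFAULT_LABEL_INTERVAL_DAYS = 7.0

#: Minimum nucleus count for a TRAP-positive cell to count as an osteoclast.
OSTEOCLAST_MIN_NUCLEI = 3


@dataclass
class CellRecord:
    cell_type: str  # "osteoblast" | "osteoclast"
    n_nuclei: int = 1


@dataclass
class HistoLabelSet:
    """Measurements for one specimen (possibly pooled over fields)."""

    interlabel_distances_um: np.ndarray
    dl_surface_mm: float
    sl_surface_mm: float
    total_bone_surface_mm: float
    interval_days: float = DEFAULT_LABEL_INTERVAL_DAYS
    cells: list[CellRecord] = field(default_factory=list)
    bone_perimeter_mm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.interlabel_distances_um = np.asarray(self.interlabel_distances_um, dtype=float)
        if self.interval_days <= 0:
            raise DataError("label interval must be positive")
        if np.any(self.interlabel_distances_um < 0):
            raise DataError("interlabel distances must be >= 0")
        if self.dl_surface_mm + self.sl_surface_mm > self.total_bone_surface_mm * (1 + 1e-9):
            raise DataError("dL + sL exceeds total bone surface")


@dataclass
class HistoReport:
    mar_um_day: float
    ms_bs: float
    bfr_bs_um3_um2_day: float
    n_ob_per_bpm: float | None = None
    n_oc_per_bpm: float | None = None


def mar(distances_um: Sequence[float], interval_days: float = DEFAULT_LABEL_INTERVAL_DAYS) -> float:
    """Mineral apposition rate: mean interlabel distance over the label interval."""
    d = np.asarray(list(distances_um), dtype=float)
    if d.size == 0:
        raise UndefinedMetricError("no interlabel distances: MAR undefined")
    if interval_days <= 0:
        raise DataError("label interval must be positive")
    return float(np.mean(d) / interval_days)


def ms_bs(dl_mm: float, sl_mm: float, bs_mm: float) -> float:
    """Mineralizing surface fraction (dL + 0.5 sL)/BS.

    Single-labeled surface counts half: it was mineralizing during only
    one of the two label windows.
    """
    if bs_mm <= 0:
        raise UndefinedMetricError("zero bone surface: MS/BS undefined")
    if dl_mm + sl_mm > bs_mm * (1 + 1e-9):
        raise DataError("dL + sL exceeds BS")
    return float((dl_mm + 0.5 * sl_mm) / bs_mm)


def bfr_bs(mar_um_day: float, ms_bs_fraction: float) -> float:
    """Surface-referent bone formation rate: MAR * MS/BS."""
    if mar_um_day < 0 or ms_bs_fraction < 0:
        raise DataError("MAR and MS/BS must be >= 0")
    return float(mar_um_day * ms_bs_fraction)


def cell_density(
    cells: Sequence[CellRecord],
    perimeter_mm: float,
    osteoclast_min_nuclei: int = OSTEOCLAST_MIN_NUCLEI,
) -> dict[str, float]:
    """Cell counts per bone perimeter (mm^-1), by cell type.

    TRAP-positive candidates with fewer than ``osteoclast_min_nuclei``
    nuclei are excluded before counting (mononuclear precursors are not
    osteoclasts).  Filtering is idempotent.
    """
    if perimeter_mm <= 0:
        raise DataError("bone perimeter must be positive")
    counts: dict[str, int] = {}
    for cell in cells:
        if cell.cell_type == "osteoclast" and cell.n_nuclei < osteoclast_min_nuclei:
            continue
        counts[cell.cell_type] = counts.get(cell.cell_type, 0) + 1
    return {ctype: n / perimeter_mm for ctype, n in counts.items()}


def histo_report(labelset: HistoLabelSet) -> HistoReport:
    """Full dynamic + cellular report for one specimen."""
    mar_value = mar(labelset.interlabel_distances_um, labelset.interval_days)
    msbs_value = ms_bs(
        labelset.dl_surface_mm, labelset.sl_surface_mm, labelset.total_bone_surface_mm
    )
    n_ob = n_oc = None
    if labelset.cells and labelset.bone_perimeter_mm:
        dens = cell_density(labelset.cells, labelset.bone_perimeter_mm)
        n_ob = dens.get("osteoblast")
        n_oc = dens.get("osteoclast")
    return HistoReport(
        mar_um_day=mar_value,
        ms_bs=msbs_value,
        bfr_bs_um3_um2_day=bfr_bs(mar_value, msbs_value),
        n_ob_per_bpm=n_ob,
        n_oc_per_bpm=n_oc,
    )
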