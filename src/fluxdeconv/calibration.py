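"""Buffer capacity, ECAR -> PPR conversion, and Clark cross-calibration.

The pH-slope readout (ECAR, mpH/min) becomes a proton production rate
(PPR, nmol H+/min) through the buffer capacity of the transient microchamber.
Buffer capacity is titrated by stepwise additions of a known quantity of HCl;
because titration may be done in the full well rather than the microchamber,
the raw slope is rescaled by the volume ratio so that PPR = ECAR / BC_chamber
holds literally.

Absolute OCR values from the plate instrument are cross-calibrated against a
Clark electrode run in parallel: the calibration factor is the ratio of the
two instruments' mean per-embryo rates, applied multiplicatively to every
plate OCR.  Fraction-of-total partitioning is invariant under this scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assay_model import DataError

__all__ = [
    "BufferCapacity",
    "CalibrationFactor",
    "buffer_capacity",
    "ecar_to_ppr",
    "clark_calibration_factor",
    "apply_calibration",
]


@dataclass(frozen=True)
class BufferCapacity:
    """Buffer capacity referred to the microchamber volume.

    ``bc_chamber`` is mpH per nmol H+ delivered into the microchamber;
    ``raw_slope`` is mpH per nmol in the titrated volume.
    """

    bc_chamber: float
    titrated_volume_uL: float
    raw_slope: float

    def __post_init__(self) -> None:
        if self.bc_chamber <= 0:
            raise DataError(f"buffer capacity must be positive, got {self.bc_chamber}")


@dataclass(frozen=True)
class CalibrationFactor:
    """Dimensionless Clark/plate rate ratio with its source means."""

    factor: float
    clark_mean: float
    xf_mean: float
    n_clark: int
    n_xf: int

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise DataError(f"calibration factor must be positive, got {self.factor}")


def buffer_capacity(
    titration_table: pd.DataFrame,
    titrated_volume_uL: float,
    chamber_volume_uL: float,
) -> BufferCapacity:
    """Buffer capacity from a stepwise acid titration table.

    The table needs columns ``cumulative_nmol_H`` and ``pH`` with at least
    3 points.  Raw slope is the negated OLS slope of pH (in mpH) against
    cumulative protons; scaling by titrated/chamber volume converts it to the
    capacity per nmol delivered into the microchamber.
    """
    if titrated_volume_uL <= 0 or chamber_volume_uL <= 0:
        raise DataError("volumes must be positive")
    for col in ("cumulative_nmol_H", "pH"):
        if col not in titration_table.columns:
            raise DataError(f"titration table is missing column {col!r}")
    cum = titration_table["cumulative_nmol_H"].to_numpy(float)
    ph = titration_table["pH"].to_numpy(float)
    if cum.size < 3:
        raise DataError(f"need at least 3 titration points, got {cum.size}")
    dph = np.diff(ph[np.argsort(cum)])
    if np.any(dph > 0):
        # small upticks can be sensor noise; a titration should acidify overall
        warnings.warn("pH is not monotonically decreasing over the titration", stacklevel=2)
    cc = cum - cum.mean()
    slope_pH = float(cc @ (ph - ph.mean())) / float(cc @ cc)  # pH per nmol
    raw_slope = -slope_pH * 1000.0  # mpH per nmol in titrated volume
    if raw_slope <= 0:
        raise DataError("titration slope is non-positive; acid additions did not lower pH")
    bc_chamber = raw_slope * titrated_volume_uL / chamber_volume_uL
    return BufferCapacity(
        bc_chamber=bc_chamber, titrated_volume_uL=titrated_volume_uL, raw_slope=raw_slope
    )


def ecar_to_ppr(ecar_mpH_min, bc: BufferCapacity):
    """PPR (nmol H+/min) = ECAR (mpH/min) / BC_chamber (mpH/nmol).

    Negative ECAR (net alkalinization) is allowed and yields a negative PPR;
    a warning flags it rather than clipping.
    """
    ecar = np.asarray(ecar_mpH_min, dtype=float)
    if np.any(ecar < 0):
        warnings.warn("negative ECAR: net alkalinization, PPR reported negative", stacklevel=2)
    ppr = ecar / bc.bc_chamber
    return float(ppr) if np.ndim(ecar_mpH_min) == 0 else ppr


def clark_calibration_factor(
    clark_rates: Sequence[float], xf_rates: Sequence[float]
) -> CalibrationFactor:
    """Calibration factor = mean(Clark) / mean(plate), per-embryo rates."""
    clark = np.asarray(list(clark_rates), float)
    xf = np.asarray(list(xf_rates), float)
    if clark.size == 0 or xf.size == 0:
        raise DataError("both instruments need at least one rate")
    if clark.mean() <= 0 or xf.mean() <= 0:
        raise DataError("mean rates must be positive for calibration")
    return CalibrationFactor(
        factor=float(clark.mean() / xf.mean()),
        clark_mean=float(clark.mean()),
        xf_mean=float(xf.mean()),
        n_clark=clark.size,
        n_xf=xf.size,
    )


def apply_calibration(rates, factor: CalibrationFactor | float):
    """Multiply plate OCRs by the calibration factor (scalar or array-safe)."""
    f = factor.factor if isinstance(factor, CalibrationFactor) else float(factor)
    if f <= 0:
        raise DataError(f"calibration factor must be positive, got {f}")
    arr = np.asarray(rates, dtype=float) * f
    return float(arr) if np.ndim(rates) == 0 else arr
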