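"""Per-cycle OCR and ECAR estimation from level traces, with QC.

Two OCR estimators are provided.  ``slope`` converts the ordinary
least-squares O2 slope over each measure phase directly to a rate,
OCR = -dO/dt * V_ch * k_O2; it ignores plate diffusion and atmospheric leak
and is therefore biased low whenever the chamber runs below its
surroundings.  ``compartment`` fits the same two-compartment model the
instrument's diffusion-aware algorithm is built on (see ``_chamber``): given
the physics constants, the chamber solution is affine in (OCR, initial O2),
so the per-cycle fit reduces to an exact linear least-squares solve.

ECAR is the negated OLS pH slope per measure phase, in mpH/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._chamber import ChamberPhysics, measure_phase_coefficients
from .assay_model import ClarkTrace, DataError, LevelTrace

__all__ = [
    "CycleRates",
    "estimate_ocr",
    "linearity_r2",
    "hypoxia_qc",
    "clark_ocr",
    "write_cycle_rates",
    "read_cycle_rates",
]

HYPOXIA_FLOOR_MMHG = 100.0


@dataclass
class CycleRates:
    """Per-cycle rate estimates for one well.

    ``valid`` marks cycles whose measure phase passed structural QC (>= 3
    samples, non-degenerate fit); invalid cycles keep NaN rates rather than
    being dropped, so cycle indices stay contiguous from 1.
    """

    well: str
    cycle: np.ndarray
    ocr_pmol_min: np.ndarray
    ecar_mpH_min: np.ndarray
    r2: np.ndarray
    min_o2_mmHg: np.ndarray
    method: str
    valid: np.ndarray
    degenerate: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well": self.well,
                "cycle": self.cycle,
                "ocr_pmol_min": self.ocr_pmol_min,
                "ecar_mpH_min": self.ecar_mpH_min,
                "r2": self.r2,
                "min_o2": self.min_o2_mmHg,
                "method": self.method,
                "qc_flag": np.where(self.valid, "ok", "invalid"),
            }
        )

    def window_values(self, first: int, last: int, field: str = "ocr_pmol_min"):
        """(values, valid) for cycles first..last inclusive."""
        mask = (self.cycle >= first) & (self.cycle <= last)
        return getattr(self, field)[mask], self.valid[mask]


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, r2) of y on t; r2 = 1 with zero residual for a flat series."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0:
        return 0.0, 1.0
    slope = float(tc @ (y - y.mean())) / denom
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return slope, 1.0  # degenerate: constant signal
    resid = y - y.mean() - slope * tc
    return slope, 1.0 - float((resid**2).sum()) / ss_tot


def _fit_compartment(physics: ChamberPhysics, t: np.ndarray, o2: np.ndarray) -> float:
    """Exact linear-least-squares OCR from one measure phase."""
    offsets = tuple(round(float(x), 9) for x in (t - t[0]))
    alpha, beta, gamma = measure_phase_coefficients(physics, offsets)
    X = np.column_stack([beta, gamma])
    theta, *_ = np.linalg.lstsq(X, o2 - alpha, rcond=None)
    return float(theta[0])


def estimate_ocr(
    trace: LevelTrace,
    physics: ChamberPhysics | None = None,
    method: str = "compartment",
) -> CycleRates:
    """Estimate OCR (pmol O2/min) and ECAR (mpH/min) for every measure cycle.

    Cycles with fewer than 3 measure samples are flagged invalid (NaN rates)
    rather than dropped; flat O2 phases are flagged degenerate with R2 = 1.
    """
    if method not in ("slope", "compartment"):
        raise ValueError(f"method must be 'slope' or 'compartment', got {method!r}")
    physics = physics or ChamberPhysics()
    cycles = trace.measure_cycles()
    if not cycles:
        raise DataError(f"{trace.well}: trace has no measure-phase samples")
    n = cycles[-1]
    ocr = np.full(n, np.nan)
    ecar = np.full(n, np.nan)
    r2 = np.full(n, np.nan)
    min_o2 = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    degen = np.zeros(n, dtype=bool)
    for cyc in cycles:
        t, o2, ph = trace.measure_samples(cyc)
        i = cyc - 1
        if t.size < 3:
            continue  # flagged invalid, never silently dropped
        slope, rsq = _ols_slope(t, o2)
        min_o2[i] = float(o2.min())
        r2[i] = rsq
        degen[i] = bool(np.ptp(o2) == 0)
        if method == "slope":
            ocr[i] = -slope * physics.v_ch_uL * physics.k_o2
        else:
            ocr[i] = _fit_compartment(physics, t, o2)
        ph_slope, _ = _ols_slope(t, ph)
        ecar[i] = -ph_slope * 1000.0  # pH/min -> mpH/min
        valid[i] = True
    return CycleRates(
        well=trace.well,
        cycle=np.arange(1, n + 1),
        ocr_pmol_min=ocr,
        ecar_mpH_min=ecar,
        r2=r2,
        min_o2_mmHg=min_o2,
        method=method,
        valid=valid,
        degenerate=degen,
    )


def linearity_r2(trace: LevelTrace, cycle: int) -> float:
    """Coefficient of determination of the OLS line through one measure phase.

    A constant-O2 phase is a degenerate fit and returns 1.0 (the line is the
    data); ``estimate_ocr`` additionally flags such cycles.
    """
    t, o2, _ = trace.measure_samples(cycle)
    if t.size < 3:
        raise DataError(f"{trace.well} cycle {cycle}: need >= 3 measure samples")
    _, rsq = _ols_slope(t, o2)
    return rsq


def hypoxia_qc(trace: LevelTrace, floor_mmHg: float = HYPOXIA_FLOOR_MMHG) -> dict[int, bool]:
    """Per-cycle pass/fail: fail when measure-phase O2 dips below the floor."""
    out: dict[int, bool] = {}
    for cyc in trace.measure_cycles():
        _, o2, _ = trace.measure_samples(cyc)
        out[cyc] = bool(o2.min() >= floor_mmHg)
    return out


def clark_ocr(trace: ClarkTrace, noise_tolerance_se: float = 3.0) -> float:
    """Per-embryo OCR (nmol O2/min/embryo) from a closed Clark-electrode trace.

    OCR = -slope(nmol/mL/min) * volume(mL) / n_embryos.  A positive slope
    beyond ``noise_tolerance_se`` standard errors is a data error: a closed
    chamber cannot gain oxygen.
    """
    if trace.time_min.size < 3:
        raise DataError("Clark trace needs at least 3 samples")
    res = sps.linregress(trace.time_min, trace.o2_nmol_per_mL)
    if res.slope > 0 and (res.stderr == 0 or res.slope > noise_tolerance_se * res.stderr):
        raise DataError(
            f"O2 concentration rises at {res.slope:.4g} nmol/mL/min; "
            "closed chamber cannot gain oxygen"
        )
    return -res.slope * trace.volume_mL / trace.n_embryos


def write_cycle_rates(rates_list, path) -> None:
    """Tidy CSV: one row per well per cycle."""
    pd.concat([r.to_frame() for r in rates_list], ignore_index=True).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_cycle_rates(path) -> pd.DataFrame:
    return pd.read_csv(path)
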