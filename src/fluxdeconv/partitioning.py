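"""Basal/treatment rate extraction and five-way respiration deconvolution.

Total basal respiration is the mean of measurement cycles five and six.
Treatment rates are two-consecutive-cycle means at the post-injection
extreme: the minimum after oligomycin or sodium azide, the maximum after
FCCP.  The five components follow directly:

    mitochondrial       R_mito    = R_basal - R_azide
    ATP turnover        R_ATP     = R_basal - R_oligo
    proton leak         R_leak    = R_oligo - R_azide
    non-mitochondrial   R_nonmito = R_azide
    maximal uncoupled   R_maxunc  = R_fccp  - R_azide

so R_mito = R_ATP + R_leak and nonmito + ATP + leak = basal hold as algebraic
identities.  Negative components are retained and flagged, never clipped:
oligomycin-derived leak is expected to scatter around zero early in
development, and testing it against zero is part of the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assay_model import N_BASAL_CYCLES, DataError

__all__ = [
    "PartitionResult",
    "CoxIvIndex",
    "basal_rate",
    "treatment_rate",
    "partition",
    "per_embryo",
    "coxiv_normalize",
    "CoxNormalizedRates",
    "carbon_loss_bound",
    "lactate_ppr_bound",
]


def _as_arrays(values, valid) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(list(values), dtype=float)
    if valid is None:
        ok = np.isfinite(v)
    else:
        ok = np.asarray(list(valid), dtype=bool) & np.isfinite(v)
    return v, ok


def basal_rate(cycle_rates: Sequence[float], valid: Sequence[bool] | None = None) -> float:
    """Total basal rate: mean of basal cycles 5 and 6.

    ``cycle_rates`` are the rates of basal cycles 1..6 in order.  If cycle 5
    or 6 failed QC, the latest two consecutive valid basal cycles are
    averaged instead, with a warning.
    """
    v, ok = _as_arrays(cycle_rates, valid)
    if v.size < N_BASAL_CYCLES:
        raise DataError(
            f"need all {N_BASAL_CYCLES} basal cycles to establish the basal rate, got {v.size}"
        )
    v, ok = v[:N_BASAL_CYCLES], ok[:N_BASAL_CYCLES]
    if ok[4] and ok[5]:
        return float((v[4] + v[5]) / 2.0)
    for i in range(N_BASAL_CYCLES - 2, -1, -1):
        if ok[i] and ok[i + 1]:
            warnings.warn(
                f"basal cycles 5/6 failed QC; using cycles {i + 1} and {i + 2}", stacklevel=2
            )
            return float((v[i] + v[i + 1]) / 2.0)
    raise DataError("no two consecutive valid basal cycles")


def treatment_rate(
    cycle_rates: Sequence[float],
    direction: str,
    valid: Sequence[bool] | None = None,
) -> float:
    """Two-consecutive-cycle mean at the post-injection extreme.

    The extreme cycle (min for inhibitors, max for uncouplers) is paired with
    whichever adjacent valid cycle gives the more extreme two-cycle mean;
    ties go to the earlier pair.
    """
    if direction not in ("min", "max"):
        raise ValueError(f"direction must be 'min' or 'max', got {direction!r}")
    v, ok = _as_arrays(cycle_rates, valid)
    idx = np.flatnonzero(ok)
    if idx.size < 2:
        raise DataError(f"need >= 2 valid post-injection cycles, got {idx.size}")
    sign = 1.0 if direction == "max" else -1.0
    ext = idx[np.argmax(sign * v[idx])]
    candidates = []
    for j in (ext - 1, ext + 1):  # earlier neighbour first: wins ties
        if j in idx:
            candidates.append((sign * (v[ext] + v[j]) / 2.0, (v[ext] + v[j]) / 2.0))
    if not candidates:
        raise DataError("extreme cycle has no valid neighbouring cycle")
    best = max(range(len(candidates)), key=lambda i: candidates[i][0])
    return float(candidates[best][1])


@dataclass
class PartitionResult:
    """The five-way deconvolution of one well's (or one stage's) respiration."""

    r_basal: float
    r_oligo: float
    r_azide: float
    r_fccp: float
    n_embryos: int = 1
    negative_components: list[str] = field(default_factory=list)

    @property
    def r_mito(self) -> float:
        return self.r_basal - self.r_azide

    @property
    def r_atp(self) -> float:
        return self.r_basal - self.r_oligo

    @property
    def r_leak(self) -> float:
        return self.r_oligo - self.r_azide

    @property
    def r_nonmito(self) -> float:
        return self.r_azide

    @property
    def r_maxunc(self) -> float:
        return self.r_fccp - self.r_azide

    def fractions(self) -> dict[str, float]:
        """nonmito/atp/leak shares of total basal respiration (sum exactly 1)."""
        if self.r_basal == 0:
            raise DataError("basal rate is zero; fractions undefined")
        return {
            "nonmito": self.r_nonmito / self.r_basal,
            "atp": self.r_atp / self.r_basal,
            "leak": self.r_leak / self.r_basal,
        }

    def per_embryo_rates(self) -> dict[str, float]:
        n = self.n_embryos
        return {
            "basal": self.r_basal / n,
            "mito": self.r_mito / n,
            "atp": self.r_atp / n,
            "leak": self.r_leak / n,
            "nonmito": self.r_nonmito / n,
            "maxunc": self.r_maxunc / n,
        }


def partition(r_basal: float, r_oligo: float, r_azide: float, r_fccp: float) -> PartitionResult:
    """Deconvolve the four extracted rates into the five components.

    Negative components are flagged in ``negative_components`` but retained.
    """
    rates = (r_basal, r_oligo, r_azide, r_fccp)
    if not all(np.isfinite(rates)):
        raise DataError(f"all four rates must be finite, got {rates}")
    res = PartitionResult(r_basal=r_basal, r_oligo=r_oligo, r_azide=r_azide, r_fccp=r_fccp)
    res.negative_components = [
        name
        for name in ("mito", "atp", "leak", "nonmito", "maxunc")
        if getattr(res, f"r_{name}") < 0
    ]
    return res


def per_embryo(result: PartitionResult, n_embryos: int) -> PartitionResult:
    """Rescale all extracted rates to a single embryo."""
    if n_embryos < 1:
        raise DataError(f"n_embryos must be >= 1, got {n_embryos}")
    out = partition(
        result.r_basal / n_embryos,
        result.r_oligo / n_embryos,
        result.r_azide / n_embryos,
        result.r_fccp / n_embryos,
    )
    out.n_embryos = 1
    return out


@dataclass(frozen=True)
class CoxIvIndex:
    """Per-stage mitochondrial-content proxy: COX IV / beta-actin densitometry,
    rescaled so the 3 hpf value is 1."""

    values: Mapping[int, float]

    def __post_init__(self) -> None:
        if 3 not in self.values or abs(self.values[3] - 1.0) > 1e-9:
            raise DataError("COX IV index must be anchored with index(3 hpf) = 1")
        if any(v <= 0 for v in self.values.values()):
            raise DataError("COX IV indices must be positive")

    @classmethod
    def from_densitometry(
        cls, cox: Mapping[int, float], actin: Mapping[int, float]
    ) -> "CoxIvIndex":
        if set(cox) != set(actin):
            raise DataError("COX IV and beta-actin tables cover different stages")
        ratio = {h: cox[h] / actin[h] for h in cox}
        anchor = ratio[3]
        return cls(values={h: r / anchor for h, r in ratio.items()})

    def __getitem__(self, hpf: int) -> float:
        try:
            return self.values[hpf]
        except KeyError:
            raise DataError(f"no COX IV index for stage {hpf} hpf") from None


@dataclass(frozen=True)
class CoxNormalizedRates:
    """Mito and maximal-uncoupled rates per unit mitochondrial content."""

    r_mito: float
    r_maxunc: float
    cox_index: float


def coxiv_normalize(result: PartitionResult, cox_index: float | CoxIvIndex, hpf: int | None = None) -> CoxNormalizedRates:
    """Divide R_mito and R_maxunc by the stage's COX IV index."""
    idx = cox_index[hpf] if isinstance(cox_index, CoxIvIndex) else float(cox_index)
    if idx <= 0:
        raise DataError(f"COX IV index must be positive, got {idx}")
    return CoxNormalizedRates(
        r_mito=result.r_mito / idx, r_maxunc=result.r_maxunc / idx, cox_index=idx
    )


def carbon_loss_bound(total_o2_nmol: float) -> float:
    """Upper bound on organic carbon loss (ug) from cumulative O2 consumption.

    Assumes pure carbohydrate oxidation (1 mol O2 per mol C):
    ug C = nmol O2 * 12 / 1000.  Lipid oxidation loses less carbon per O2,
    so this is a ceiling.
    """
    if total_o2_nmol < 0:
        raise DataError(f"total O2 must be non-negative, got {total_o2_nmol}")
    return total_o2_nmol * 12.0 / 1000.0


def lactate_ppr_bound(
    detection_limit_uM: float,
    media_volume_mL: float,
    n_embryos: int,
    duration_min: float,
    measured_ppr: float | None = None,
) -> tuple[float, float | None]:
    """Ceiling on the lactate contribution to acid extrusion.

    If no lactate is detectable, the largest rate compatible with the assay is
    limit(uM = nmol/mL) * volume(mL) / (duration(min) * n_embryos), in
    nmol H+/min/embryo (one proton per lactate).  Returns (bound, fraction of
    the measured PPR, or None if that PPR is non-positive).
    """
    if detection_limit_uM < 0 or media_volume_mL <= 0 or n_embryos < 1 or duration_min <= 0:
        raise DataError("detection limit must be >= 0 and volume/count/duration positive")
    bound = detection_limit_uM * media_volume_mL / (duration_min * n_embryos)
    if measured_ppr is None:
        return bound, None
    if measured_ppr <= 0:
        warnings.warn("measured PPR is non-positive; lactate fraction undefined", stacklevel=2)
        return bound, None
    return bound, bound / measured_ppr
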