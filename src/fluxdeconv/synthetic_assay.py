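"""Ground-truthed synthetic instrument data for the whole pipeline.

Generates XF-style plate runs (level traces of O2 and pH over mix/wait/measure
cycles with injections), closed-chamber Clark-electrode traces, inhibitor
dose-response curves, and buffer-capacity titration tables.  Every simulator
takes an explicit seed and returns the ground truth needed to score recovery,
so the analysis stages can be tested end to end without an instrument.

The stage-parameter defaults encode the developmental profile the pipeline is
built around: per-embryo basal OCR rising linearly with hours
post-fertilization through 91 pmol O2/min at 30 hpf, proton-leak fractions of
0 / 0 / 0.27 / 0.27 / 0.18 / 0.094 at 3 / 7 / 12 / 24 / 30 / 48 hpf, an
elevated non-mitochondrial share early in development, and an FCCP-uncoupled
maximum peaking around gastrulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import assay_model as am
from ._chamber import ChamberPhysics, chamber_o2
from .assay_model import (
    ClarkTrace,
    ConfigError,
    InjectionSchedule,
    LevelTrace,
    PlateLayout,
    PlateRun,
    ScheduleError,
)

__all__ = [
    "SyntheticStageParams",
    "ChamberPhysics",
    "TitrationCurve",
    "default_stage_table",
    "simulate_plate",
    "simulate_clark_run",
    "simulate_titration",
    "simulate_buffer_titration",
    "MEASURE_OFFSETS",
    "MIX_OFFSETS",
    "WAIT_OFFSETS",
]


@dataclass(frozen=True)
class SyntheticStageParams:
    """Ground-truth bioenergetic parameters for one developmental stage.

    ``basal_ocr_pmol_min`` and ``basal_ppr_nmol_min`` are per embryo.  The
    fractions split total basal respiration into non-mitochondrial, proton
    leak and ATP-turnover components and must sum to 1; ``fccp_fold`` scales
    *mitochondrial* respiration under full uncoupling.  CVs are lognormal
    multiplicative spreads for well-to-well and clutch-to-clutch variation.
    """

    hpf: int
    basal_ocr_pmol_min: float
    f_nonmito: float
    f_leak: float
    f_atp: float
    fccp_fold: float
    basal_ppr_nmol_min: float
    well_cv: float = 0.10
    clutch_cv: float = 0.10
    fccp_ppr_multiplier: float = 1.0

    def __post_init__(self) -> None:
        fs = (self.f_nonmito, self.f_leak, self.f_atp)
        if any(f < 0 or f > 1 for f in fs):
            raise ConfigError(f"{self.hpf} hpf: fractions must lie in [0, 1], got {fs}")
        if abs(sum(fs) - 1.0) > 1e-9:
            raise ConfigError(f"{self.hpf} hpf: fractions must sum to 1, got {sum(fs)}")
        if self.basal_ocr_pmol_min <= 0 or self.basal_ppr_nmol_min <= 0:
            raise ConfigError(f"{self.hpf} hpf: basal OCR and PPR must be positive")
        if self.well_cv < 0 or self.clutch_cv < 0:
            raise ConfigError(f"{self.hpf} hpf: CVs must be non-negative")

    @property
    def f_mito(self) -> float:
        return self.f_leak + self.f_atp

    def phase_ocr(self, window: str) -> float:
        """True per-embryo OCR (pmol/min) during a named treatment window."""
        total = self.basal_ocr_pmol_min
        if window == "basal":
            return total
        if window == "oligomycin":
            return (self.f_nonmito + self.f_leak) * total
        if window == "fccp":
            return self.f_nonmito * total + self.fccp_fold * self.f_mito * total
        if window in ("sodium_azide", "rotenone", "antimycin_a"):
            return self.f_nonmito * total
        raise ConfigError(f"unknown treatment window {window!r}")

    def phase_ppr(self, window: str) -> float:
        if window == "fccp":
            return self.basal_ppr_nmol_min * self.fccp_ppr_multiplier
        return self.basal_ppr_nmol_min

    def noiseless(self) -> "SyntheticStageParams":
        return replace(self, well_cv=0.0, clutch_cv=0.0)


# Basal OCR ramp: linear in hpf, anchored at 91 pmol/min per embryo at 30 hpf
# (the Clark-electrode cross-calibration stage) with ~15 pmol/min at 3 hpf.
_OCR_SLOPE = (91.0 - 15.0) / (30.0 - 3.0)
_OCR_INTERCEPT = 15.0 - 3.0 * _OCR_SLOPE

_LEAK = {3: 0.0, 7: 0.0, 12: 0.27, 24: 0.27, 30: 0.18, 48: 0.094}
_NONMITO = {3: 0.55, 7: 0.40, 12: 0.25, 24: 0.25, 30: 0.25, 48: 0.25}
_FCCP_FOLD = {3: 1.5, 7: 1.8, 12: 1.7, 24: 1.6, 30: 1.5, 48: 1.4}


def default_stage_table(**overrides) -> dict[int, SyntheticStageParams]:
    """Stage -> ground-truth parameters for the six assayed timepoints.

    Keyword overrides (e.g. ``well_cv=0.0``) are applied to every stage;
    per-stage replacement is a matter of rebuilding entries with
    :func:`dataclasses.replace`.
    """
    table: dict[int, SyntheticStageParams] = {}
    for hpf in am.ASSAYED_STAGES:
        params = SyntheticStageParams(
            hpf=hpf,
            basal_ocr_pmol_min=_OCR_INTERCEPT + _OCR_SLOPE * hpf,
            f_nonmito=_NONMITO[hpf],
            f_leak=_LEAK[hpf],
            f_atp=round(1.0 - _NONMITO[hpf] - _LEAK[hpf], 12),
            fccp_fold=_FCCP_FOLD[hpf],
            basal_ppr_nmol_min=0.04 * hpf + 0.08,
        )
        if overrides:
            params = replace(params, **overrides)
        table[hpf] = params
    return table


# ---------------------------------------------------------------------------
# Plate simulation
# ---------------------------------------------------------------------------

# Sample offsets (min) from cycle start within each phase of the
# 2 min mix / 1 min wait / 1.5 min measure template.
MIX_OFFSETS = (0.0, 1.0)
WAIT_OFFSETS = (2.0,)
MEASURE_OFFSETS = tuple(round(3.0 + 0.2 * k, 6) for k in range(8))
_MEASURE_REL = tuple(round(o - 3.0, 6) for o in MEASURE_OFFSETS)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _bulk_o2(o0: float, rate_mmHg_min: float, k_s: float, o_atm: float, dt: float) -> float:
    """Well-bulk O2 after dt minutes of consumption plus surface aeration."""
    if k_s <= 0:
        return o0 - rate_mmHg_min * dt
    o_eq = o_atm - rate_mmHg_min / k_s
    return o_eq + (o0 - o_eq) * math.exp(-k_s * dt)


def _window_for_cycle(windows: list[tuple[str, int, int]], cycle: int) -> str:
    for label, lo, hi in windows:
        if lo <= cycle <= hi:
            return label
    return windows[-1][0]


def simulate_plate(
    stage_hpf: int,
    layout: PlateLayout | None = None,
    schedule: InjectionSchedule | None = None,
    physics: ChamberPhysics | None = None,
    seed: int = 0,
    stage_params: SyntheticStageParams | None = None,
    n_cycles: int = 24,
) -> tuple[PlateRun, pd.DataFrame]:
    """Simulate one full plate run and return it with its truth record.

    Per sample well the true OCR follows the stage parameters, switching at
    each scheduled injection; the chamber O2 during measure phases follows the
    exact two-compartment solution; pH falls at PPR * BC during measure
    phases; mix phases re-equilibrate chamber and wall to well bulk.  The
    returned truth record has one row per well per treatment window with the
    realised (noise-scaled) true well rates and the stage fractions.
    """
    physics = physics or ChamberPhysics()
    layout = layout or PlateLayout.default_islet(stage_hpf)
    schedule = schedule or InjectionSchedule.default_stress_test(stage_hpf, n_cycles)
    params = stage_params or default_stage_table()[stage_hpf]
    if any(p.cycle > n_cycles for p in schedule.ports):
        raise ScheduleError("injection cycle beyond the end of the run")

    rng = np.random.default_rng(seed)
    clutch = _lognormal_factor(rng, params.clutch_cv)
    windows = schedule.windows(n_cycles)

    traces: dict[str, LevelTrace] = {}
    truth_rows: list[dict] = []
    for well in am.ALL_WELLS:
        n_emb = layout.n_embryos[well] if layout.roles[well] == "sample" else 0
        well_factor = _lognormal_factor(rng, params.well_cv) * clutch if n_emb else 1.0

        # realised true well rates per window
        well_ocr = {
            label: n_emb * well_factor * params.phase_ocr(label) for label, _, _ in windows
        }
        well_ppr = {
            label: n_emb * well_factor * params.phase_ppr(label) for label, _, _ in windows
        }
        for label, lo, hi in windows:
            truth_rows.append(
                {
                    "well": well,
                    "role": layout.roles[well],
                    "n_embryos": n_emb,
                    "window": label,
                    "cycle_start": lo,
                    "cycle_end": hi,
                    "true_ocr_pmol_min": well_ocr[label],
                    "true_ppr_nmol_min": well_ppr[label],
                    "f_nonmito": params.f_nonmito,
                    "f_leak": params.f_leak,
                    "f_atp": params.f_atp,
                    "well_factor": well_factor * (1 if n_emb else 0),
                }
            )

        times, o2s, phs, cycles, phases = [], [], [], [], []
        o_bulk = physics.o_atm_mmHg
        cum_h_nmol = 0.0  # protons accumulated in the full well
        bc_well = physics.bc_chamber * physics.v_ch_uL / physics.well_volume_uL
        t_prev = 0.0
        for cyc in range(1, n_cycles + 1):
            label = _window_for_cycle(windows, cyc)
            ocr = well_ocr[label]
            ppr = well_ppr[label]
            rate_bulk = ocr / (physics.well_volume_uL * physics.k_o2)  # mmHg/min
            t0 = (cyc - 1) * am.CYCLE_MIN

            # open phases: sensor raised, chamber contents = well bulk
            for off, phase in [(o, "mix") for o in MIX_OFFSETS] + [
                (o, "wait") for o in WAIT_OFFSETS
            ]:
                t = t0 + off
                o_bulk = _bulk_o2(o_bulk, rate_bulk, physics.k_surface, physics.o_atm_mmHg, t - t_prev)
                cum_h_nmol += ppr * (t - t_prev)
                t_prev = t
                times.append(t)
                o2s.append(o_bulk)
                phs.append(physics.ph0 - cum_h_nmol * bc_well / 1000.0)
                cycles.append(cyc)
                phases.append(phase)

            # measure phase: microchamber forms, wall equilibrated with bulk
            t_m = t0 + 3.0
            o_bulk = _bulk_o2(o_bulk, rate_bulk, physics.k_surface, physics.o_atm_mmHg, t_m - t_prev)
            cum_h_nmol += ppr * (t_m - t_prev)
            t_prev = t_m
            ph_start = physics.ph0 - cum_h_nmol * bc_well / 1000.0
            o_ch = chamber_o2(physics, _MEASURE_REL, ocr, o_bulk)
            for k, rel in enumerate(_MEASURE_REL):
                t = t_m + rel
                times.append(t)
                o2s.append(float(o_ch[k]))
                phs.append(ph_start - ppr * physics.bc_chamber * rel / 1000.0)
                cycles.append(cyc)
                phases.append("measure")
            # bulk keeps evolving through the measure window (chamber volume
            # is negligible relative to the 700 uL well)
            t_end = t_m + _MEASURE_REL[-1]
            o_bulk = _bulk_o2(o_bulk, rate_bulk, physics.k_surface, physics.o_atm_mmHg, t_end - t_m)
            cum_h_nmol += ppr * (t_end - t_m)
            t_prev = t_end

        o2 = np.asarray(o2s)
        ph = np.asarray(phs)
        if physics.o2_noise_sd > 0:
            o2 = o2 + rng.normal(0.0, physics.o2_noise_sd, o2.size)
        if physics.ph_noise_sd > 0:
            ph = ph + rng.normal(0.0, physics.ph_noise_sd, ph.size)
        traces[well] = LevelTrace(
            well=well,
            time_min=np.asarray(times),
            o2_mmHg=np.clip(o2, 0.0, None),
            ph=ph,
            cycle=np.asarray(cycles),
            phase=np.asarray(phases, dtype=object),
        )

    run = PlateRun(layout=layout, schedule=schedule, traces=traces, stage_hpf=stage_hpf)
    return run, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Clark electrode
# ---------------------------------------------------------------------------


def simulate_clark_run(
    true_ocr_per_embryo_pmol_min: float,
    n_embryos: int,
    volume_mL: float = 1.5,
    seed: int = 0,
    duration_min: float = 10.0,
    dt_min: float = 0.5,
    noise_sd_nmol_mL: float = 0.05,
    c0_nmol_mL: float = 240.0,
) -> ClarkTrace:
    """Closed-chamber dissolved-O2 decline at n * OCR / volume, plus sensor noise.

    ``c0_nmol_mL`` defaults to air-saturated fresh water at 28.5 C.
    """
    if volume_mL <= 0:
        raise ConfigError(f"chamber volume must be positive, got {volume_mL}")
    if true_ocr_per_embryo_pmol_min <= 0 or n_embryos < 1:
        raise ConfigError("OCR and embryo count must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    slope = n_embryos * true_ocr_per_embryo_pmol_min / 1000.0 / volume_mL  # nmol/mL/min
    conc = c0_nmol_mL - slope * t
    if noise_sd_nmol_mL > 0:
        conc = conc + rng.normal(0.0, noise_sd_nmol_mL, t.size)
    return ClarkTrace(volume_mL=volume_mL, n_embryos=n_embryos, time_min=t, o2_nmol_per_mL=conc)


# ---------------------------------------------------------------------------
# Drug titrations
# ---------------------------------------------------------------------------


@dataclass
class TitrationCurve:
    """Dose-response table for one agent at one stage: |dOCR| vs dose."""

    agent: str
    stage_hpf: int
    doses: np.ndarray
    responses: np.ndarray
    dead: np.ndarray  # bool: death within the assay timeframe

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose": self.doses,
                "response": self.responses,
                "death_flag": self.dead.astype(int),
            }
        )


@dataclass(frozen=True)
class _AgentDoseModel:
    ec50: float
    hill: float
    rmax: float
    death_threshold_early: float  # stages 3-12 hpf
    death_threshold_late: float  # stages 24-48 hpf


# Hill parameters chosen so the maximal non-lethal response falls on the
# standard working concentrations (oligomycin 9.4 uM; FCCP 1.875 / 2.5 uM;
# azide 6.25 / 1.25 mM depending on stage band).
_AGENT_MODELS = {
    "oligomycin": _AgentDoseModel(ec50=2.0, hill=1.5, rmax=40.0, death_threshold_early=15.0, death_threshold_late=15.0),
    "fccp": _AgentDoseModel(ec50=1.2, hill=2.0, rmax=60.0, death_threshold_early=2.2, death_threshold_late=3.0),
    "sodium_azide": _AgentDoseModel(ec50=0.5, hill=1.0, rmax=80.0, death_threshold_early=10.0, death_threshold_late=10.0),
}
# sodium azide's stage split is inverted relative to FCCP: 48 hpf embryos
# tolerate far less, so the "late" threshold is the low one.
_AZIDE_LATE_THRESHOLD = 2.0


def _death_threshold(agent: str, stage_hpf: int) -> float:
    model = _AGENT_MODELS[agent]
    if agent == "sodium_azide":
        return _AZIDE_LATE_THRESHOLD if stage_hpf >= 48 else model.death_threshold_early
    return model.death_threshold_early if stage_hpf <= 12 else model.death_threshold_late


def simulate_titration(
    agent: str,
    stage_hpf: int,
    doses,
    seed: int = 0,
    noise_cv: float = 0.03,
) -> TitrationCurve:
    """Monotone saturating |dOCR| response with a death threshold.

    Response is Hill-shaped in dose; wells above the agent/stage death
    threshold are flagged dead (their measured response is still reported).
    """
    doses = np.asarray(list(doses), dtype=float)
    if doses.size == 0:
        raise ConfigError("dose list must not be empty")
    if np.any(doses < 0) or np.any(np.diff(doses) <= 0):
        raise ConfigError("doses must be positive and strictly increasing")
    if agent not in _AGENT_MODELS:
        raise ConfigError(f"unknown agent {agent!r}; known: {sorted(_AGENT_MODELS)}")
    model = _AGENT_MODELS[agent]
    rng = np.random.default_rng(seed)
    resp = model.rmax * doses**model.hill / (model.ec50**model.hill + doses**model.hill)
    if noise_cv > 0:
        resp = resp * (1.0 + rng.normal(0.0, noise_cv, doses.size))
    dead = doses > _death_threshold(agent, stage_hpf)
    return TitrationCurve(agent=agent, stage_hpf=stage_hpf, doses=doses, responses=resp, dead=dead)


# ---------------------------------------------------------------------------
# Buffer-capacity titration
# ---------------------------------------------------------------------------


def simulate_buffer_titration(
    bc_true_mpH_per_nmol: float,
    volume_uL: float = 700.0,
    n_additions: int = 5,
    nmol_per_addition: float = 1000.0,  # 10 uL of 0.1 N HCl
    seed: int = 0,
    ph0: float = 7.0,
    noise_sd_pH: float = 0.0005,
) -> pd.DataFrame:
    """Stepwise HCl additions into the titrated volume; returns the pH table.

    ``bc_true_mpH_per_nmol`` is the buffer capacity *of the titrated volume*.
    The table has a baseline row plus one row per addition, with columns
    ``cumulative_nmol_H`` and ``pH``.
    """
    if n_additions < 2:
        raise ConfigError(f"need at least 2 acid additions, got {n_additions}")
    if bc_true_mpH_per_nmol <= 0 or volume_uL <= 0 or nmol_per_addition <= 0:
        raise ConfigError("buffer capacity, volume and addition size must be positive")
    rng = np.random.default_rng(seed)
    cum = np.arange(n_additions + 1) * nmol_per_addition
    ph = ph0 - bc_true_mpH_per_nmol * cum / 1000.0
    if noise_sd_pH > 0:
        ph = ph + rng.normal(0.0, noise_sd_pH, ph.size)
    return pd.DataFrame({"cumulative_nmol_H": cum, "pH": ph})
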