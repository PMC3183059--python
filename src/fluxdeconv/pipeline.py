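"""End-to-end developmental profiling: generator -> rates -> calibration ->
partitioning -> statistics, under a single reproducible configuration.

``run_pipeline`` simulates (or loads) one plate per requested developmental
stage, estimates per-cycle OCR/ECAR, applies the Clark calibration factor,
extracts basal and treatment rates, deconvolves the five respiration
components per well, converts ECAR to PPR, and runs the stage comparisons
(ANOVA + SNK across stages, per-stage proton-leak t-test against zero).  All
randomness flows from the config seed; identical configs produce identical
reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assay_model as am
from ._chamber import ChamberPhysics
from .assay_model import ConfigError, DataError, InjectionSchedule, PlateRun
from .calibration import BufferCapacity, apply_calibration
from .partitioning import basal_rate, partition, treatment_rate
from .rate_estimation import estimate_ocr, hypoxia_qc
from .stats import GroupComparison, TTestResult, anova_snk, t_test_vs_zero
from .synthetic_assay import default_stage_table, simulate_plate

__all__ = ["RunConfig", "PipelineResult", "QCAbort", "run_pipeline", "fit_development_trend"]

log = logging.getLogger("fluxdeconv")


class QCAbort(RuntimeError):
    """Raised when a stage fails hypoxia QC on more than half its wells."""

    def __init__(self, message: str, report: pd.DataFrame | None = None):
        super().__init__(message)
        self.report = report


@dataclass
class RunConfig:
    """Everything a reproducible run needs; round-trips to YAML losslessly."""

    stages: tuple[int, ...] = am.ASSAYED_STAGES
    seed: int = 0
    physics: ChamberPhysics = field(default_factory=ChamberPhysics)
    stage_param_overrides: dict = field(default_factory=dict)  # applied to every stage
    calibration_factor: float = 1.0
    method: str = "compartment"
    n_cycles: int = 24
    n_clutches: int = 1  # independent plate runs (breeding pairs) per stage
    hypoxia_floor_mmHg: float = 100.0
    qc_abort_fraction: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.stages = tuple(int(h) for h in self.stages)
        for h in self.stages:
            am.stage_config(h)  # raises UnknownStageError early
        if self.calibration_factor <= 0:
            raise ConfigError("calibration factor must be positive")
        if self.method not in ("slope", "compartment"):
            raise ConfigError(f"method must be 'slope' or 'compartment', got {self.method!r}")

    def stage_seed(self, index: int) -> int:
        return (int(self.seed) * 1000 + index) % (2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "physics" in d and isinstance(d["physics"], dict):
            d["physics"] = ChamberPhysics(**d["physics"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    """Per-well report, per-stage aggregates, and the stage statistics."""

    wells: pd.DataFrame
    stage_summary: pd.DataFrame
    basal_comparison: GroupComparison | None
    leak_fraction_comparison: GroupComparison | None
    leak_tests: dict[int, TTestResult]
    trend: tuple[float, float, float] | None  # slope, intercept, R2 of basal vs hpf
    config: RunConfig

    def summary_text(self) -> str:
        lines = ["fluxdeconv developmental profile", "=" * 34]
        lines.append(self.stage_summary.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
        if self.trend is not None:
            s, b, r2 = self.trend
            lines.append(
                f"\nbasal OCR vs hpf: slope {s:.4g} pmol/min/embryo/hpf, "
                f"intercept {b:.4g}, R2 {r2:.6f}"
            )
        for hpf, res in sorted(self.leak_tests.items()):
            verdict = "differs from zero" if res.significant else "not different from zero"
            lines.append(
                f"leak fraction at {hpf} hpf: t = {res.t:.3g}, p = {res.p:.3g} ({verdict})"
            )
        if self.basal_comparison is not None:
            lines.append("\nper-embryo basal OCR across stages:")
            lines.append(self.basal_comparison.summary())
        if self.leak_fraction_comparison is not None:
            lines.append("\nleak fraction across stages:")
            lines.append(self.leak_fraction_comparison.summary())
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.wells.to_csv(outdir / "wells.csv", index=False, float_format="%.6f")
        self.stage_summary.to_csv(outdir / "stage_summary.csv", index=False, float_format="%.6f")
        (outdir / "summary.txt").write_text(self.summary_text(), encoding="utf-8")
        self.config.to_yaml(outdir / "run_config.yaml")


def _windows_by_agent(schedule: InjectionSchedule, n_cycles: int) -> dict[str, tuple[int, int]]:
    return {label: (lo, hi) for label, lo, hi in schedule.windows(n_cycles)}


def profile_plate(
    run: PlateRun,
    config: RunConfig,
    bc: BufferCapacity | None = None,
) -> pd.DataFrame:
    """Per-well rate extraction and partitioning for one plate run.

    Returns one row per sample well with raw rates, the five components,
    per-embryo values, fractions of total, PPR, and QC flags.  Wells failing
    hypoxia QC in any measure cycle are flagged and excluded by downstream
    aggregation; if more than ``qc_abort_fraction`` of sample wells fail,
    :class:`QCAbort` is raised.
    """
    wins = _windows_by_agent(run.schedule, config.n_cycles)
    for needed in ("basal", "oligomycin", "sodium_azide", "fccp"):
        if needed not in wins:
            raise ConfigError(f"schedule lacks a {needed!r} window; cannot partition")
    bc_chamber = bc.bc_chamber if bc is not None else config.physics.bc_chamber

    rows = []
    sample_wells = [w for w in run.layout.sample_wells if w in run.traces]
    n_fail = 0
    for well in sample_wells:
        trace = run.traces[well]
        rates = estimate_ocr(trace, config.physics, method=config.method)
        ocr = apply_calibration(rates.ocr_pmol_min, config.calibration_factor)
        qc = hypoxia_qc(trace, config.hypoxia_floor_mmHg)
        hypoxic = not all(qc.values())
        if hypoxic:
            n_fail += 1

        bas_v, bas_ok = rates.window_values(*wins["basal"])
        r_basal = basal_rate(apply_calibration(bas_v, config.calibration_factor), bas_ok)
        extracted = {}
        for agent, direction in (("oligomycin", "min"), ("sodium_azide", "min"), ("fccp", "max")):
            v, ok = rates.window_values(*wins[agent])
            extracted[agent] = treatment_rate(
                apply_calibration(v, config.calibration_factor), direction, ok
            )
        res = partition(r_basal, extracted["oligomycin"], extracted["sodium_azide"], extracted["fccp"])
        n_emb = run.layout.n_embryos[well]
        res.n_embryos = n_emb
        fr = res.fractions()

        ecar_b, ecar_ok = rates.window_values(*wins["basal"], field="ecar_mpH_min")
        basal_ecar = basal_rate(ecar_b, ecar_ok)
        basal_ppr = basal_ecar / bc_chamber

        rows.append(
            {
                "stage_hpf": run.stage_hpf,
                "well": well,
                "n_embryos": n_emb,
                "r_basal": r_basal,
                "r_oligo": extracted["oligomycin"],
                "r_azide": extracted["sodium_azide"],
                "r_fccp": extracted["fccp"],
                "r_mito": res.r_mito,
                "r_atp": res.r_atp,
                "r_leak": res.r_leak,
                "r_nonmito": res.r_nonmito,
                "r_maxunc": res.r_maxunc,
                "basal_per_embryo": r_basal / n_emb,
                "leak_per_embryo": res.r_leak / n_emb,
                "frac_nonmito": fr["nonmito"],
                "frac_atp": fr["atp"],
                "frac_leak": fr["leak"],
                "basal_ecar_mpH_min": basal_ecar,
                "basal_ppr_nmol_min": basal_ppr,
                "ppr_per_embryo": basal_ppr / n_emb,
                "min_o2_mmHg": float(np.nanmin(rates.min_o2_mmHg)),
                "qc_hypoxia_fail": hypoxic,
                "negative_components": ";".join(res.negative_components),
            }
        )
    df = pd.DataFrame(rows)
    if sample_wells and n_fail / len(sample_wells) > config.qc_abort_fraction:
        raise QCAbort(
            f"stage {run.stage_hpf} hpf: {n_fail}/{len(sample_wells)} wells below the "
            f"{config.hypoxia_floor_mmHg} mmHg floor",
            report=df,
        )
    return df


def run_pipeline(config: RunConfig, plates: dict[int, PlateRun] | None = None) -> PipelineResult:
    """Run the full profile over the configured stages.

    ``plates`` maps stage -> loaded PlateRun to analyze recorded data; stages
    without an entry are simulated with the default stage-parameter table
    (plus ``config.stage_param_overrides``) at the stage-derived seed.
    """
    log.info("pipeline start: stages=%s seed=%s method=%s", config.stages, config.seed, config.method)
    log.info("physics: %s", config.physics)
    log.info("calibration factor: %s", config.calibration_factor)
    table = default_stage_table(**config.stage_param_overrides)

    per_stage: list[pd.DataFrame] = []
    for idx, hpf in enumerate(config.stages):
        if plates and hpf in plates:
            df = profile_plate(plates[hpf], config)
            df["clutch"] = 0
            per_stage.append(df)
            continue
        for clutch in range(config.n_clutches):
            seed = config.stage_seed(idx * config.n_clutches + clutch)
            log.info("simulating stage %s hpf, clutch %s, seed %s", hpf, clutch, seed)
            run, _ = simulate_plate(
                hpf,
                physics=config.physics,
                seed=seed,
                stage_params=table[hpf],
                n_cycles=config.n_cycles,
            )
            df = profile_plate(run, config)
            df["clutch"] = clutch
            per_stage.append(df)
    wells = pd.concat(per_stage, ignore_index=True)
    good = wells[~wells["qc_hypoxia_fail"]]

    agg = (
        good.groupby("stage_hpf")
        .agg(
            n_wells=("well", "size"),
            basal_per_embryo_mean=("basal_per_embryo", "mean"),
            basal_per_embryo_sem=("basal_per_embryo", "sem"),
            ppr_per_embryo_mean=("ppr_per_embryo", "mean"),
            ppr_per_embryo_sem=("ppr_per_embryo", "sem"),
            frac_nonmito_mean=("frac_nonmito", "mean"),
            frac_atp_mean=("frac_atp", "mean"),
            frac_leak_mean=("frac_leak", "mean"),
            frac_leak_sem=("frac_leak", "sem"),
        )
        .reset_index()
        .sort_values("stage_hpf")
    )

    basal_cmp = leak_cmp = None
    if len(config.stages) >= 2:
        basal_groups = {int(h): g["basal_per_embryo"].to_numpy() for h, g in good.groupby("stage_hpf")}
        leak_groups = {int(h): g["frac_leak"].to_numpy() for h, g in good.groupby("stage_hpf")}
        if all(v.size >= 2 for v in basal_groups.values()):
            basal_cmp = anova_snk(basal_groups, alpha=config.alpha)
            leak_cmp = anova_snk(leak_groups, alpha=config.alpha)

    leak_tests = {
        int(h): t_test_vs_zero(g["frac_leak"].to_numpy(), alpha=config.alpha)
        for h, g in good.groupby("stage_hpf")
        if g.shape[0] >= 2 and g["frac_leak"].std(ddof=1) > 0
    }

    trend = None
    if agg.shape[0] >= 3:
        trend = fit_development_trend(
            dict(zip(agg["stage_hpf"], agg["basal_per_embryo_mean"]))
        )
    log.info("pipeline done: %d wells across %d stages", wells.shape[0], len(config.stages))
    return PipelineResult(
        wells=wells,
        stage_summary=agg,
        basal_comparison=basal_cmp,
        leak_fraction_comparison=leak_cmp,
        leak_tests=leak_tests,
        trend=trend,
        config=config,
    )


def fit_development_trend(stage_means) -> tuple[float, float, float]:
    """OLS of per-embryo basal rate against hpf: (slope, intercept, R2)."""
    if isinstance(stage_means, dict):
        hpf = np.asarray(sorted(stage_means), float)
        y = np.asarray([stage_means[h] for h in sorted(stage_means)], float)
    else:
        arr = np.asarray(list(stage_means), float)
        hpf, y = arr[:, 0], arr[:, 1]
    if hpf.size < 3:
        raise DataError(f"need >= 3 stages for a trend fit, got {hpf.size}")
    slope, intercept = np.polyfit(hpf, y, 1)
    pred = slope * hpf + intercept
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(((y - pred) ** 2).sum()) / ss_tot
    return float(slope), float(intercept), r2
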