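"""Domain types and tabular I/O for 24-well extracellular-flux plate runs.

The assay plates modelled here are 24-well "islet" microplates (rows A-D,
columns 1-6).  Four wells are specimen-free temperature controls; the
remaining 20 hold staged zebrafish embryos under capture screens.  Each
measurement cycle is a fixed mix / wait / measure template during which a
transient microchamber forms over the specimen and O2 tension (mmHg) and pH
are logged.  Up to four injection ports deliver inhibitors at scheduled
cycles after six basal cycles.

Everything here is plain data plus validation; no rate arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "LayoutError",
    "DataError",
    "ScheduleError",
    "ConfigError",
    "UnknownStageError",
    "ROWS",
    "N_COLS",
    "ALL_WELLS",
    "DEFAULT_CONTROL_WELLS",
    "MIX_MIN",
    "WAIT_MIN",
    "MEASURE_MIN",
    "CYCLE_MIN",
    "N_BASAL_CYCLES",
    "StageConfig",
    "stage_config",
    "ASSAYED_STAGES",
    "PlateLayout",
    "validate_layout",
    "InjectionPort",
    "InjectionSchedule",
    "LevelTrace",
    "PlateRun",
    "ClarkTrace",
    "load_plate_run",
    "write_plate_run",
    "read_level_frame",
    "traces_from_frame",
    "load_clark_trace",
    "write_clark_trace",
]


class FormatError(ValueError):
    """A delimited input file does not match the expected format."""


class LayoutError(ValueError):
    """Well identifiers or roles are inconsistent with the 24-well plate."""


class DataError(ValueError):
    """Values violate a physical or ordering constraint."""


class ScheduleError(ValueError):
    """An injection schedule is inconsistent with the cycle structure."""


class ConfigError(ValueError):
    """A configuration value is out of its allowed range."""


class UnknownStageError(KeyError):
    """Requested developmental stage was not one of the assayed timepoints."""


# ---------------------------------------------------------------------------
# Plate geometry and cycle template
# ---------------------------------------------------------------------------

ROWS = "ABCD"
N_COLS = 6
ALL_WELLS: tuple[str, ...] = tuple(f"{r}{c}" for r in ROWS for c in range(1, N_COLS + 1))
DEFAULT_CONTROL_WELLS: tuple[str, ...] = ("A1", "B3", "C4", "D6")

# Cycle template: 2 min mix, 1 min wait, 1.5 min measure.
MIX_MIN = 2.0
WAIT_MIN = 1.0
MEASURE_MIN = 1.5
CYCLE_MIN = MIX_MIN + WAIT_MIN + MEASURE_MIN
N_BASAL_CYCLES = 6

_WELL_RE = re.compile(r"^([A-Da-d])([1-6])$")


def normalize_well(well: str) -> str:
    """Canonical upper-case well ID; raises LayoutError off the A-D x 1-6 grid."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise LayoutError(f"well {well!r} is not on the 24-well grid (rows A-D, columns 1-6)")
    return m.group(1).upper() + m.group(2)


# ---------------------------------------------------------------------------
# Developmental-stage lookup
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageConfig:
    """Assay parameters for one assayed developmental timepoint.

    ``embryos_per_well`` is the plating density that keeps OCR in range while
    O2 stays above the hypoxia floor; FCCP/azide concentrations are the
    titration-selected maximal non-lethal doses for that stage band.
    """

    hpf: int
    name: str
    embryos_per_well: int
    fccp_uM: float
    azide_mM: float
    oligomycin_uM: float = 9.4


_STAGE_TABLE: dict[int, StageConfig] = {
    3: StageConfig(3, "Blastula", 3, fccp_uM=1.875, azide_mM=6.25),
    7: StageConfig(7, "Gastrula", 2, fccp_uM=1.875, azide_mM=6.25),
    12: StageConfig(12, "Segmentation", 2, fccp_uM=1.875, azide_mM=6.25),
    24: StageConfig(24, "Segmentation/Pharyngula Transition", 2, fccp_uM=2.5, azide_mM=6.25),
    30: StageConfig(30, "Mid-Pharyngula", 2, fccp_uM=2.5, azide_mM=6.25),
    48: StageConfig(48, "Hatching", 1, fccp_uM=2.5, azide_mM=1.25),
}

ASSAYED_STAGES: tuple[int, ...] = tuple(sorted(_STAGE_TABLE))


def stage_config(hpf: int) -> StageConfig:
    """Look up the stage table; refuses non-tabulated timepoints (no interpolation)."""
    try:
        return _STAGE_TABLE[int(hpf)]
    except (KeyError, TypeError, ValueError):
        raise UnknownStageError(
            f"no assayed stage at {hpf} hpf; tabulated stages are {ASSAYED_STAGES}"
        ) from None


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------


@dataclass
class PlateLayout:
    """Roles and plating densities for all 24 wells of one plate.

    ``roles`` maps well -> "sample" | "temperature_control"; control wells
    must carry zero embryos.  ``stage_hpf`` is per-well so mixed-stage plates
    can be represented, though the standard runs are single-stage.
    """

    plate_type: str = "islet"
    roles: dict[str, str] = field(default_factory=dict)
    n_embryos: dict[str, int] = field(default_factory=dict)
    stage_hpf: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.plate_type not in ("islet", "V28"):
            raise ConfigError(f"plate_type must be 'islet' or 'V28', got {self.plate_type!r}")
        self.roles = {normalize_well(w): r for w, r in self.roles.items()}
        self.n_embryos = {normalize_well(w): int(n) for w, n in self.n_embryos.items()}
        self.stage_hpf = {normalize_well(w): int(h) for w, h in self.stage_hpf.items()}
        if set(self.roles) != set(ALL_WELLS):
            missing = sorted(set(ALL_WELLS) - set(self.roles))
            extra = sorted(set(self.roles) - set(ALL_WELLS))
            raise LayoutError(f"layout must cover exactly 24 wells (missing {missing}, extra {extra})")
        for w, n in self.n_embryos.items():
            if n < 0:
                raise LayoutError(f"well {w}: n_embryos must be non-negative, got {n}")

    @classmethod
    def default_islet(
        cls,
        stage_hpf: int,
        n_embryos: int | None = None,
        control_wells: Sequence[str] = DEFAULT_CONTROL_WELLS,
    ) -> "PlateLayout":
        """Standard single-stage islet layout: 4 control wells, 20 sample wells."""
        if n_embryos is None:
            n_embryos = stage_config(stage_hpf).embryos_per_well
        controls = {normalize_well(w) for w in control_wells}
        roles = {w: ("temperature_control" if w in controls else "sample") for w in ALL_WELLS}
        counts = {w: (0 if w in controls else int(n_embryos)) for w in ALL_WELLS}
        stages = {w: int(stage_hpf) for w in ALL_WELLS}
        return cls(roles=roles, n_embryos=counts, stage_hpf=stages)

    @property
    def sample_wells(self) -> list[str]:
        return [w for w in ALL_WELLS if self.roles[w] == "sample"]

    @property
    def control_wells(self) -> list[str]:
        return [w for w in ALL_WELLS if self.roles[w] == "temperature_control"]

    def to_dict(self) -> dict:
        return {
            "plate_type": self.plate_type,
            "wells": {
                w: {
                    "role": self.roles[w],
                    "n_embryos": self.n_embryos.get(w, 0),
                    "stage_hpf": self.stage_hpf.get(w),
                }
                for w in ALL_WELLS
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlateLayout":
        wells = d["wells"]
        return cls(
            plate_type=d.get("plate_type", "islet"),
            roles={w: v["role"] for w, v in wells.items()},
            n_embryos={w: v.get("n_embryos", 0) for w, v in wells.items()},
            stage_hpf={w: v.get("stage_hpf") for w, v in wells.items() if v.get("stage_hpf") is not None},
        )


def validate_layout(layout: PlateLayout) -> list[str]:
    """Return a list of layout issues (empty iff the layout is standard).

    Checks the temperature-control convention: exactly four control wells,
    each with zero embryos, and every sample well holding at least one embryo.
    Issues are returned, never raised.
    """
    issues: list[str] = []
    controls = layout.control_wells
    if len(controls) != 4:
        issues.append(f"expected 4 temperature control wells, found {len(controls)}")
    for w in controls:
        if layout.n_embryos.get(w, 0) != 0:
            issues.append(f"temperature control well {w} must contain no embryos "
                          f"(has {layout.n_embryos[w]})")
    for w in layout.sample_wells:
        if layout.n_embryos.get(w, 0) < 1:
            issues.append(f"sample well {w} has no embryos")
    return issues


# ---------------------------------------------------------------------------
# Injection schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InjectionPort:
    agent: str
    concentration: float
    units: str
    cycle: int  # first measurement cycle run after this injection (1-based)


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered injection ports; all injections follow the six basal cycles."""

    ports: tuple[InjectionPort, ...]

    def __post_init__(self) -> None:
        if len(self.ports) > 4:
            raise ScheduleError("at most 4 injection ports are available")
        prev = N_BASAL_CYCLES
        for p in self.ports:
            if p.concentration <= 0:
                raise ScheduleError(f"{p.agent}: concentration must be positive")
            if p.cycle <= N_BASAL_CYCLES:
                raise ScheduleError(
                    f"{p.agent}: injection cycle {p.cycle} precedes the end of the "
                    f"{N_BASAL_CYCLES} basal cycles"
                )
            if p.cycle <= prev and p is not self.ports[0]:
                raise ScheduleError("injection cycle indices must be strictly increasing")
            prev = p.cycle

    @classmethod
    def default_stress_test(cls, hpf: int, n_cycles: int = 24) -> "InjectionSchedule":
        """Oligomycin -> FCCP -> sodium azide at stage-appropriate doses.

        Six post-injection cycles per agent inside the standard 6 + 18 cycle
        run; concentrations come from the stage table.
        """
        sc = stage_config(hpf)
        step = max(2, (n_cycles - N_BASAL_CYCLES) // 3)
        c0 = N_BASAL_CYCLES + 1
        return cls(
            ports=(
                InjectionPort("oligomycin", sc.oligomycin_uM, "uM", c0),
                InjectionPort("fccp", sc.fccp_uM, "uM", c0 + step),
                InjectionPort("sodium_azide", sc.azide_mM, "mM", c0 + 2 * step),
            )
        )

    def windows(self, n_cycles: int) -> list[tuple[str, int, int]]:
        """(label, first_cycle, last_cycle) for basal and each post-injection span."""
        out = [("basal", 1, min(N_BASAL_CYCLES, n_cycles))]
        for i, p in enumerate(self.ports):
            last = self.ports[i + 1].cycle - 1 if i + 1 < len(self.ports) else n_cycles
            out.append((p.agent, p.cycle, min(last, n_cycles)))
        return out

    def to_dict(self) -> dict:
        return {
            "ports": [
                {"agent": p.agent, "concentration": p.concentration, "units": p.units, "cycle": p.cycle}
                for p in self.ports
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "InjectionSchedule":
        return cls(
            ports=tuple(
                InjectionPort(p["agent"], float(p["concentration"]), p["units"], int(p["cycle"]))
                for p in d["ports"]
            )
        )


# ---------------------------------------------------------------------------
# Level traces
# ---------------------------------------------------------------------------

_PHASES = ("mix", "wait", "measure")


@dataclass
class LevelTrace:
    """Raw per-well time series of O2 tension and pH with cycle/phase labels."""

    well: str
    time_min: np.ndarray
    o2_mmHg: np.ndarray
    ph: np.ndarray
    cycle: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.well = normalize_well(self.well)
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.o2_mmHg = np.asarray(self.o2_mmHg, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        self.cycle = np.asarray(self.cycle, dtype=int)
        self.phase = np.asarray(self.phase, dtype=object)
        n = self.time_min.size
        for name in ("o2_mmHg", "ph", "cycle", "phase"):
            if getattr(self, name).size != n:
                raise DataError(f"{self.well}: column {name} length mismatch")
        if n and np.any(np.diff(self.time_min) <= 0):
            raise DataError(f"{self.well}: time must be strictly increasing")
        if np.any(self.o2_mmHg < 0):
            raise DataError(f"{self.well}: negative O2 tension")
        bad = set(self.phase) - set(_PHASES)
        if bad:
            raise DataError(f"{self.well}: unknown phase labels {sorted(bad)}")

    def measure_cycles(self) -> list[int]:
        mask = self.phase == "measure"
        return sorted(np.unique(self.cycle[mask]).tolist())

    def measure_samples(self, cycle: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mask = (self.phase == "measure") & (self.cycle == int(cycle))
        return self.time_min[mask], self.o2_mmHg[mask], self.ph[mask]


@dataclass
class PlateRun:
    """One plate assay: layout, injection schedule, and a trace per well."""

    layout: PlateLayout
    schedule: InjectionSchedule
    traces: dict[str, LevelTrace]
    stage_hpf: int | None = None

    def wells(self) -> list[str]:
        return sorted(self.traces, key=ALL_WELLS.index)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for w in self.wells():
            t = self.traces[w]
            parts.append(
                pd.DataFrame(
                    {
                        "well": w,
                        "time_min": t.time_min,
                        "cycle": t.cycle,
                        "phase": t.phase,
                        "O2_mmHg": t.o2_mmHg,
                        "pH": t.ph,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Clark-electrode traces
# ---------------------------------------------------------------------------


@dataclass
class ClarkTrace:
    """Closed-chamber dissolved-O2 record (nmol/mL) from a Clark electrode cell."""

    volume_mL: float
    n_embryos: int
    time_min: np.ndarray
    o2_nmol_per_mL: np.ndarray

    def __post_init__(self) -> None:
        if self.volume_mL <= 0:
            raise ConfigError(f"chamber volume must be positive, got {self.volume_mL}")
        if self.n_embryos < 1:
            raise ConfigError(f"n_embryos must be >= 1, got {self.n_embryos}")
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.o2_nmol_per_mL = np.asarray(self.o2_nmol_per_mL, dtype=float)
        if self.time_min.size != self.o2_nmol_per_mL.size:
            raise DataError("time and concentration columns differ in length")
        if self.time_min.size and np.any(np.diff(self.time_min) <= 0):
            raise DataError("time must be strictly increasing")


# ---------------------------------------------------------------------------
# File I/O (comma-delimited, header required, UTF-8)
# ---------------------------------------------------------------------------

_PLATE_COLUMNS = ("well", "time_min", "cycle", "phase", "O2_mmHg", "pH")


def read_level_frame(path: str | Path) -> pd.DataFrame:
    """Read a long-format plate-run CSV, checking the required columns."""
    df = pd.read_csv(path)
    for col in _PLATE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"plate-run file {path} is missing required column {col!r}")
    return df


def traces_from_frame(df: pd.DataFrame) -> dict[str, LevelTrace]:
    traces: dict[str, LevelTrace] = {}
    for well, sub in df.groupby("well", sort=False):
        w = normalize_well(well)
        sub = sub.sort_values("time_min", kind="stable")
        traces[w] = LevelTrace(
            well=w,
            time_min=sub["time_min"].to_numpy(),
            o2_mmHg=sub["O2_mmHg"].to_numpy(),
            ph=sub["pH"].to_numpy(),
            cycle=sub["cycle"].to_numpy(),
            phase=sub["phase"].to_numpy(),
        )
    return traces


def _coerce_layout(layout_config) -> tuple[PlateLayout, InjectionSchedule | None, int | None]:
    if isinstance(layout_config, PlateLayout):
        return layout_config, None, None
    if isinstance(layout_config, (str, Path)):
        with open(layout_config, "r", encoding="utf-8") as fh:
            layout_config = yaml.safe_load(fh)
    if not isinstance(layout_config, Mapping):
        raise ConfigError("layout_config must be a PlateLayout, a mapping, or a YAML/JSON path")
    layout = PlateLayout.from_dict(layout_config["layout"] if "layout" in layout_config else layout_config)
    schedule = None
    if "schedule" in layout_config:
        schedule = InjectionSchedule.from_dict(layout_config["schedule"])
    stage = layout_config.get("stage_hpf")
    return layout, schedule, stage


def load_plate_run(
    path: str | Path,
    layout_config,
    schedule: InjectionSchedule | None = None,
) -> PlateRun:
    """Load a long-format plate-run CSV against a layout/schedule config.

    ``layout_config`` is a :class:`PlateLayout`, a dict, or a path to a YAML
    config holding ``layout`` (and optionally ``schedule`` / ``stage_hpf``)
    sections.  Rows are sorted by well then time; wells absent from the layout
    raise :class:`LayoutError`, non-monotone time raises :class:`DataError`.
    """
    layout, cfg_schedule, stage = _coerce_layout(layout_config)
    schedule = schedule or cfg_schedule
    if schedule is None:
        raise ConfigError("no injection schedule supplied (argument or config 'schedule' section)")
    df = read_level_frame(path)
    traces = traces_from_frame(df)
    for w in traces:
        if w not in layout.roles:
            raise LayoutError(f"trace well {w} is not present in the layout")
    return PlateRun(layout=layout, schedule=schedule, traces=traces, stage_hpf=stage)


def write_plate_run(run: PlateRun, path: str | Path) -> None:
    """Write the run's traces as tidy CSV (well, time_min, cycle, phase, O2_mmHg, pH)."""
    run.to_frame().to_csv(path, index=False, float_format="%.6f")


def write_clark_trace(trace: ClarkTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_min": trace.time_min, "O2_nmol_per_mL": trace.o2_nmol_per_mL}
    ).to_csv(path, index=False, float_format="%.6f")


def load_clark_trace(path: str | Path, volume_mL: float, n_embryos: int) -> ClarkTrace:
    df = pd.read_csv(path)
    for col in ("time_min", "O2_nmol_per_mL"):
        if col not in df.columns:
            raise FormatError(f"Clark trace file {path} is missing required column {col!r}")
    return ClarkTrace(
        volume_mL=volume_mL,
        n_embryos=n_embryos,
        time_min=df["time_min"].to_numpy(),
        o2_nmol_per_mL=df["O2_nmol_per_mL"].to_numpy(),
    )
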