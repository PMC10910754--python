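"""Seeded synthetic 384-well screens with known dose-response ground truth.

Each treated well's noise-free endpoint growth is the inverse of the NGR
mapping applied to the target GR curve: r >= 0 maps to r * neg_growth and
r < 0 maps to -r * pos_growth, so pushing a noise-free plate back through
the NGR pipeline reproduces the generating curve exactly.  Trajectories
between timepoints interpolate (1 + G) geometrically; measurement noise is
multiplicative lognormal on areas.

Control magnitudes (vehicle doubling, staurosporine kill fraction) are
plausible stand-ins, not published values; downstream results are invariant
to them in the noise-free case because NGR only uses ratios to controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .dose_response import gr_model
from .errors import ConfigError
from .plate_io import (
    CSV_COLUMNS,
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    ExperimentTable,
)
import pandas as pd

#: 7-point logarithmic titration from 1 to 5000 nM.
DEFAULT_DOSE_GRID = np.logspace(0.0, math.log10(5000.0), 7)

#: Imaging every 24 h up to 120 h, plus the pre-treatment baseline.
DEFAULT_TIMEPOINTS = np.arange(0.0, 121.0, 24.0)

_PLATE_ROWS = "ABCDEFGHIJKLMNOP"
_PLATE_CAPACITY = 384


@dataclass(frozen=True)
class DoseResponseTruth:
    """Ground-truth GR parameters for one cell line x drug."""

    grinf: float
    gec50: float
    hill: float

    def validate(self) -> None:
        if not -1.0 <= self.grinf <= 1.0:
            raise ConfigError(f"GRinf {self.grinf} outside [-1, 1]")
        if not self.gec50 > 0:
            raise ConfigError(f"GEC50 {self.gec50} must be > 0")
        if not self.hill > 0:
            raise ConfigError(f"Hill coefficient {self.hill} must be > 0")


@dataclass
class SimulationConfig:
    """Full description of one simulated plate."""

    truth: Mapping[tuple[str, str], DoseResponseTruth]
    dose_grid: np.ndarray = field(default_factory=lambda: DEFAULT_DOSE_GRID.copy())
    timepoints: np.ndarray = field(default_factory=lambda: DEFAULT_TIMEPOINTS.copy())
    neg_growth: float = 1.0
    pos_growth: float = -0.9
    noise_cv: float = 0.0
    wells_per_dose: int = 4
    n_control_wells: int = 16
    v0: float = 1000.0
    plate_id: str = "SIM1"
    culture: str = "3D"
    focal_line: str | None = None
    seed: int = 0

    def validate(self) -> None:
        grid = np.asarray(self.dose_grid, dtype=float)
        if len(grid) < 4 or np.any(np.diff(grid) <= 0) or np.any(grid <= 0):
            raise ConfigError("dose_grid must be strictly increasing, > 0, length >= 4")
        if not self.neg_growth > 0:
            raise ConfigError("neg_growth must be > 0 (vehicle control must grow)")
        if not self.pos_growth < 0:
            raise ConfigError("pos_growth must be < 0 (positive control must die)")
        if self.pos_growth <= -1.0:
            raise ConfigError("pos_growth must be > -1 (some residual area remains)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.wells_per_dose < 1 or self.n_control_wells < 1:
            raise ConfigError("wells_per_dose and n_control_wells must be >= 1")
        if self.v0 <= 0:
            raise ConfigError("v0 must be > 0")
        ts = np.asarray(self.timepoints, dtype=float)
        if len(ts) < 2 or ts[0] != 0 or np.any(np.diff(ts) <= 0):
            raise ConfigError("timepoints must start at 0 and increase")
        if not self.truth:
            raise ConfigError("truth must contain at least one (cell_line, drug)")
        for key, t in self.truth.items():
            if len(key) != 2:
                raise ConfigError(f"truth key {key!r} must be (cell_line, drug)")
            t.validate()
        n_needed = 2 * self.n_control_wells + len(self.truth) * len(grid) * (
            self.wells_per_dose
        )
        if n_needed > _PLATE_CAPACITY:
            raise ConfigError(f"layout needs {n_needed} wells > {_PLATE_CAPACITY}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        truth = {
            (entry["cell_line"], entry["drug"]): DoseResponseTruth(
                grinf=float(entry["grinf"]),
                gec50=float(entry["gec50"]),
                hill=float(entry["hill"]),
            )
            for entry in raw.pop("truth")
        }
        for key in ("dose_grid", "timepoints"):
            if key in raw:
                raw[key] = np.asarray(raw[key], dtype=float)
        return cls(truth=truth, **raw)

    def to_dict(self) -> dict:
        return dict(
            truth=[
                dict(cell_line=cl, drug=dr, grinf=t.grinf, gec50=t.gec50, hill=t.hill)
                for (cl, dr), t in sorted(self.truth.items())
            ],
            dose_grid=[float(x) for x in self.dose_grid],
            timepoints=[float(x) for x in self.timepoints],
            neg_growth=self.neg_growth,
            pos_growth=self.pos_growth,
            noise_cv=self.noise_cv,
            wells_per_dose=self.wells_per_dose,
            n_control_wells=self.n_control_wells,
            v0=self.v0,
            plate_id=self.plate_id,
            culture=self.culture,
            focal_line=self.focal_line,
            seed=self.seed,
        )


def target_growth(r: float, neg_growth: float, pos_growth: float) -> float:
    """Endpoint growth that the NGR mapping sends back to the curve value r."""
    return r * neg_growth if r >= 0 else -r * pos_growth


def _well_name(index: int) -> str:
    return f"{_PLATE_ROWS[index // 24]}{index % 24 + 1:02d}"


def _trajectory(v0: float, g_end: float, timepoints: np.ndarray, horizon: float):
    """Geometric interpolation of viability between baseline and endpoint."""
    base = max(1.0 + g_end, 1e-12)
    return v0 * base ** (timepoints / horizon)


def simulate_plate(config: SimulationConfig) -> ExperimentTable:
    """Generate one plate; identical config (incl. seed) gives identical output.

    Dead-cell area is modeled as the shortfall of viability against the
    vehicle-like growth potential, so viability = total - dead reproduces
    the growth model and total brightfield area never shrinks on kill.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = np.asarray(config.dose_grid, dtype=float)
    ts = np.asarray(config.timepoints, dtype=float)
    horizon = float(ts[-1])
    sigma = math.sqrt(math.log1p(config.noise_cv**2))

    def noisy(values: np.ndarray) -> np.ndarray:
        if config.noise_cv == 0:
            return values
        mult = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=values.shape)
        return values * mult

    rows: list[dict] = []
    idx = 0

    def emit(cell_line, drug, conc, rep, g_end):
        nonlocal idx
        well = _well_name(idx)
        idx += 1
        viability = _trajectory(config.v0, g_end, ts, horizon)
        potential = _trajectory(config.v0, config.neg_growth, ts, horizon)
        dead = np.maximum(0.0, potential - viability)
        total = noisy(viability + dead)
        dead = noisy(dead)
        for t, tot, dd in zip(ts, total, dead):
            rows.append(
                dict(
                    plate_id=config.plate_id,
                    well=well,
                    cell_line=cell_line,
                    drug=drug,
                    concentration_nM=float(conc),
                    timepoint_h=float(t),
                    total_area=float(tot),
                    dead_area=float(dd),
                    replicate_id=rep,
                )
            )

    control_line = sorted({cl for cl, _ in config.truth})[0]
    for i in range(config.n_control_wells):
        emit(control_line, NEGATIVE_CONTROL, 0.0, f"c{i + 1}", config.neg_growth)
    for i in range(config.n_control_wells):
        emit(control_line, POSITIVE_CONTROL, 0.0, f"c{i + 1}", config.pos_growth)

    for (cell_line, drug), truth in sorted(config.truth.items()):
        r = gr_model(grid, truth.grinf, truth.gec50, truth.hill)
        for conc, r_c in zip(grid, r):
            g_end = target_growth(float(r_c), config.neg_growth, config.pos_growth)
            for w in range(config.wells_per_dose):
                emit(cell_line, drug, conc, f"r{w + 1}", g_end)

    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return ExperimentTable(df, grid)


def default_scenarios() -> dict[str, SimulationConfig]:
    """Named, seeded scenario library spanning the qualitative regimes.

    Every scenario includes a "wildtype" baseline line so the comparison
    stage of the pipeline can run end-to-end against it.
    """
    wt = DoseResponseTruth(grinf=-0.6, gec50=30.0, hill=2.0)
    noise = 0.05
    scenarios = {
        "wt_3d_sensitive": SimulationConfig(
            truth={
                ("wildtype", "tki"): wt,
                ("near_wildtype", "tki"): DoseResponseTruth(-0.5, 60.0, 2.0),
            },
            focal_line="wildtype",
            plate_id="WT3D",
            noise_cv=noise,
            seed=101,
        ),
        "g2032r_like_resistant": SimulationConfig(
            truth={
                ("wildtype", "tki"): wt,
                ("solvent_front_mutant", "tki"): DoseResponseTruth(0.3, 1800.0, 1.5),
            },
            focal_line="solvent_front_mutant",
            plate_id="RES3D",
            noise_cv=noise,
            seed=102,
        ),
        "cytostatic_plateau": SimulationConfig(
            truth={
                ("wildtype", "tki"): wt,
                ("plateau_line", "tki"): DoseResponseTruth(0.0, 100.0, 2.0),
            },
            focal_line="plateau_line",
            plate_id="CYT3D",
            noise_cv=noise,
            seed=103,
        ),
        "2d_attenuated": SimulationConfig(
            truth={
                ("wildtype", "tki"): DoseResponseTruth(-0.2, 300.0, 1.5),
                ("solvent_front_mutant", "tki"): DoseResponseTruth(0.35, 2500.0, 1.2),
            },
            focal_line="wildtype",
            plate_id="ATT2D",
            culture="2D",
            noise_cv=noise,
            seed=104,
        ),
    }
    return scenarios


def scenario(name: str, seed: int | None = None) -> SimulationConfig:
    """Look up a scenario by name, optionally overriding its seed."""
    lib = default_scenarios()
    if name not in lib:
        raise ConfigError(f"unknown scenario {name!r}; choose from {sorted(lib)}")
    cfg = lib[name]
    return replace(cfg, seed=seed) if seed is not None else cfg
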