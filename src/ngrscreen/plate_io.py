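"""Read, validate and write long-format well-level measurement tables.

The single interchange format is a tidy CSV with one row per well per
timepoint and the exact columns in :data:`CSV_COLUMNS`.  Concentrations are
stored in nM, areas are unitless (only ratios matter downstream).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    IntegrityError,
    MeasurementError,
    SchemaError,
    ValidationError,
)

#: Exact column set of the interchange CSV.
CSV_COLUMNS = [
    "plate_id",
    "well",
    "cell_line",
    "drug",
    "concentration_nM",
    "timepoint_h",
    "total_area",
    "dead_area",
    "replicate_id",
]

#: Columns that carry raw measurements (must always be present in the CSV).
MEASUREMENT_COLUMNS = ["plate_id", "well", "timepoint_h", "total_area", "dead_area"]

#: Columns that may alternatively be supplied by a plate map.
ANNOTATION_COLUMNS = ["cell_line", "drug", "concentration_nM", "replicate_id"]

#: Drug labels reserved for control wells.
NEGATIVE_CONTROL = "vehicle"
POSITIVE_CONTROL = "positive_control"
CONTROL_DRUGS = (NEGATIVE_CONTROL, POSITIVE_CONTROL)

_WELL_RE = re.compile(r"^[A-P](0[1-9]|1[0-9]|2[0-4])$")

#: Relative tolerance for dose-grid membership of treated concentrations.
GRID_RTOL = 1e-9


@dataclass(frozen=True)
class WellRecord:
    """One timestamped measurement of one well."""

    plate_id: str
    well: str
    cell_line: str
    drug: str
    concentration_nM: float
    timepoint_h: float
    total_area: float
    dead_area: float
    replicate_id: str


@dataclass
class ExperimentTable:
    """Validated collection of well records plus the declared dose design.

    ``records`` is a :class:`pandas.DataFrame` with columns
    :data:`CSV_COLUMNS`; ``dose_grid`` is ascending and strictly positive.
    """

    records: pd.DataFrame
    dose_grid: np.ndarray
    timepoints: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.records = self.records.loc[:, CSV_COLUMNS].reset_index(drop=True)
        self.dose_grid = np.asarray(self.dose_grid, dtype=float)
        if self.timepoints is None:
            self.timepoints = np.sort(self.records["timepoint_h"].unique())
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        validate_table(self.records, self.dose_grid)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentTable):
            return NotImplemented
        key = ["plate_id", "well", "timepoint_h"]
        a = self.records.sort_values(key).reset_index(drop=True)
        b = other.records.sort_values(key).reset_index(drop=True)
        return a.equals(b) and np.array_equal(self.dose_grid, other.dose_grid)

    @classmethod
    def from_records(
        cls, records: Iterable[WellRecord], dose_grid: Sequence[float]
    ) -> "ExperimentTable":
        df = pd.DataFrame([r.__dict__ for r in records], columns=CSV_COLUMNS)
        return cls(df, np.asarray(dose_grid, dtype=float))

    def to_records(self) -> list[WellRecord]:
        return [WellRecord(**row) for row in self.records.to_dict("records")]


@dataclass
class PlateMap:
    """Maps wells to cell line / drug / role and declares the dose grid.

    ``wells`` maps a well name to a dict with keys ``cell_line``, ``drug``,
    ``concentration_nM`` and ``replicate_id``.
    """

    dose_grid: np.ndarray
    wells: Mapping[str, dict]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PlateMap":
        if "dose_grid" not in raw:
            raise SchemaError("plate map must declare 'dose_grid'")
        dose_grid = np.asarray(raw["dose_grid"], dtype=float)
        wells: dict[str, dict] = {}
        for block in raw.get("blocks", []):
            names = expand_well_range(block["wells"])
            role = block.get("role", "treated")
            if role == "negative_control":
                assign = dict(drug=NEGATIVE_CONTROL, concentration_nM=0.0)
            elif role == "positive_control":
                assign = dict(drug=POSITIVE_CONTROL, concentration_nM=0.0)
            elif role == "treated":
                assign = dict(drug=block["drug"])
            else:
                raise ValidationError(f"unknown role {role!r} in plate map block")
            base = dict(
                cell_line=block.get("cell_line", "unknown"),
                replicate_id=str(block.get("replicate_id", "r1")),
                **assign,
            )
            if role == "treated":
                if block.get("dose_series", False):
                    if len(names) != len(dose_grid):
                        raise ValidationError(
                            f"dose_series block {block['wells']!r} has {len(names)} "
                            f"wells but the grid has {len(dose_grid)} doses"
                        )
                    for name, dose in zip(names, dose_grid):
                        wells[name] = dict(base, concentration_nM=float(dose))
                    continue
                base["concentration_nM"] = float(block["concentration_nM"])
            for name in names:
                wells[name] = dict(base)
        return cls(dose_grid=dose_grid, wells=wells)


def expand_well_range(spec: str) -> list[str]:
    """Expand ``"B02:D04"`` into the rectangular block of well names."""
    parts = spec.split(":")
    if len(parts) == 1:
        if not _WELL_RE.match(spec):
            raise ValidationError(f"malformed well name {spec!r}")
        return [spec]
    lo, hi = parts
    if not (_WELL_RE.match(lo) and _WELL_RE.match(hi)):
        raise ValidationError(f"malformed well range {spec!r}")
    r0, r1 = ord(lo[0]), ord(hi[0])
    c0, c1 = int(lo[1:]), int(hi[1:])
    if r1 < r0 or c1 < c0:
        raise ValidationError(f"inverted well range {spec!r}")
    return [f"{chr(r)}{c:02d}" for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)]


def _check_grid(dose_grid: np.ndarray) -> None:
    if dose_grid.ndim != 1 or len(dose_grid) == 0:
        raise ValidationError("dose grid must be a non-empty 1-D sequence")
    if np.any(dose_grid <= 0):
        raise ValidationError("dose grid concentrations must all be > 0")
    if np.any(np.diff(dose_grid) <= 0):
        raise ValidationError("dose grid must be sorted strictly ascending")


def on_grid(conc: np.ndarray, dose_grid: np.ndarray) -> np.ndarray:
    """Boolean mask of which concentrations match a grid dose (rtol 1e-9)."""
    conc = np.atleast_1d(np.asarray(conc, dtype=float))
    return np.array(
        [bool(np.any(np.isclose(c, dose_grid, rtol=GRID_RTOL, atol=0.0))) for c in conc]
    )


def validate_table(df: pd.DataFrame, dose_grid: np.ndarray) -> None:
    """Raise a typed error on any contract violation; never drop rows."""
    _check_grid(dose_grid)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    bad_wells = [w for w in df["well"].unique() if not _WELL_RE.match(str(w))]
    if bad_wells:
        raise ValidationError(f"malformed well names (expect A01..P24): {bad_wells}")

    key = df[["plate_id", "well", "timepoint_h"]]
    dup_mask = key.duplicated(keep=False)
    if dup_mask.any():
        dups = key[dup_mask].drop_duplicates()
        labels = [f"{p}/{w}/{t:g}" for p, w, t in dups.itertuples(index=False)]
        raise IntegrityError(
            f"duplicate (plate, well, timepoint) rows: {sorted(set(labels))}"
        )

    for col in ("total_area", "dead_area"):
        if (df[col] < 0).any():
            bad = df.loc[df[col] < 0, ["plate_id", "well", "timepoint_h"]]
            raise MeasurementError(
                f"negative {col} in rows: "
                f"{[f'{p}/{w}/{t:g}' for p, w, t in bad.itertuples(index=False)]}"
            )
    if (df["concentration_nM"] < 0).any():
        raise MeasurementError("negative concentration_nM")
    if (df["timepoint_h"] < 0).any():
        raise MeasurementError("negative timepoint_h")

    is_control = df["drug"].isin(CONTROL_DRUGS)
    if (df.loc[is_control, "concentration_nM"] != 0).any():
        raise ValidationError("control wells must carry concentration 0")

    treated = df.loc[~is_control]
    if len(treated):
        mask = on_grid(treated["concentration_nM"].to_numpy(), dose_grid)
        if not mask.all():
            off = sorted(set(treated.loc[~mask, "concentration_nM"]))
            raise ValidationError(
                f"treated concentrations not on the declared dose grid: {off}"
            )


def read_measurements(
    path: str | Path, plate_map: PlateMap | Mapping | str | Path | None = None
) -> ExperimentTable:
    """Read a long-format measurement CSV into a validated ExperimentTable.

    If ``plate_map`` is given, annotation columns (cell line, drug, dose,
    replicate) are taken from the map; wells referenced in the CSV but absent
    from the map are rejected with a report of the offending wells.  Without
    a map the CSV must carry the full column set and the dose grid is
    inferred from the treated concentrations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip parsing so write -> read is bit-exact on float fields
    df = pd.read_csv(path, float_precision="round_trip")

    if isinstance(plate_map, (str, Path)):
        plate_map = PlateMap.from_yaml(plate_map)
    elif isinstance(plate_map, Mapping):
        plate_map = PlateMap.from_dict(plate_map)

    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    if plate_map is not None:
        unmapped = sorted(set(df["well"]) - set(plate_map.wells))
        if unmapped:
            raise ValidationError(
                f"wells present in the CSV but not in the plate map: {unmapped}"
            )
        ann = pd.DataFrame.from_dict(plate_map.wells, orient="index")
        ann.index.name = "well"
        df = df.drop(columns=[c for c in ANNOTATION_COLUMNS if c in df.columns])
        df = df.merge(ann.reset_index(), on="well", how="left")
        dose_grid = plate_map.dose_grid
    else:
        for col in ANNOTATION_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        treated = df.loc[~df["drug"].isin(CONTROL_DRUGS), "concentration_nM"]
        dose_grid = np.sort(treated.unique()) if len(treated) else np.array([1.0])

    df["plate_id"] = df["plate_id"].astype(str)
    df["well"] = df["well"].astype(str)
    df["cell_line"] = df["cell_line"].astype(str)
    df["drug"] = df["drug"].astype(str)
    df["replicate_id"] = df["replicate_id"].astype(str)
    for col in ("concentration_nM", "timepoint_h", "total_area", "dead_area"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)

    return ExperimentTable(df, dose_grid)


def write_measurements(table: ExperimentTable, path: str | Path) -> None:
    """Write the table as CSV; ``read_measurements`` round-trips it exactly."""
    validate_table(table.records, table.dose_grid)
    table.records.loc[:, CSV_COLUMNS].to_csv(path, index=False)
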