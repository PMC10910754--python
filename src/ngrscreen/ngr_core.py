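"""Viability, fractional growth and the clipped normalized growth rate (NGR).

Per well: viability V = max(0, total area - dead area); fractional growth
G = (V(x) - V(0)) / V(0).  Treated growth is normalized against the median
growth of the plate's own controls at the same timepoint:

    NGR = G_drug / Gmed_neg      if G_drug > 0
    NGR = -(G_drug / Gmed_pos)   if G_drug < 0
    NGR = 0                      if G_drug == 0

then clipped to [-1, 1].  The negative branch carries an explicit sign
correction so that growth matching the positive (killing) control maps to
-1 and the vehicle control maps to +1; see README for why the published
formula's sign is taken as a typesetting loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateWellError, MissingControlError, PlateQCError
from .plate_io import (
    CONTROL_DRUGS,
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    ExperimentTable,
)

#: Tolerance used when classifying NGR values against the anchor points.
CLASS_TOL = 1e-6


@dataclass(frozen=True)
class GrowthValue:
    """Fractional growth of one well at one timepoint."""

    plate_id: str
    well: str
    G: float
    timepoint_h: float


@dataclass(frozen=True)
class ControlSummary:
    """Median control growths for one plate at one timepoint.

    QC requires the vehicle control to grow (Gmed_neg > 0) and the positive
    control to shrink (Gmed_pos < 0); otherwise the plate cannot anchor the
    NGR scale.
    """

    gmed_neg: float
    gmed_pos: float
    n_neg: int
    n_pos: int
    timepoint_h: float


def compute_viability(total_area, dead_area):
    """Viability = total area minus dead-cell area, floored at 0.

    Flooring absorbs segmentation noise where the dead-cell mask exceeds the
    brightfield mask.  Accepts scalars or arrays.
    """
    return np.maximum(0.0, np.asarray(total_area, dtype=float) - dead_area)


def compute_growth(v0: float, vx: float) -> float:
    """Fractional growth (vx - v0) / v0; requires positive baseline."""
    if v0 <= 0:
        raise DegenerateWellError(
            f"baseline viability {v0} is not positive; growth undefined"
        )
    return (vx - v0) / v0


def summarize_controls(growths: pd.DataFrame, timepoint_h: float) -> ControlSummary:
    """Median G of vehicle and positive-control wells of a single plate.

    ``growths`` needs columns ``drug`` and ``G`` and must already be
    restricted to one plate and one timepoint.
    """
    neg = growths.loc[growths["drug"] == NEGATIVE_CONTROL, "G"]
    pos = growths.loc[growths["drug"] == POSITIVE_CONTROL, "G"]
    if len(neg) == 0:
        raise MissingControlError("no vehicle-control wells at this timepoint")
    if len(pos) == 0:
        raise MissingControlError("no positive-control wells at this timepoint")
    summary = ControlSummary(
        gmed_neg=float(neg.median()),
        gmed_pos=float(pos.median()),
        n_neg=int(len(neg)),
        n_pos=int(len(pos)),
        timepoint_h=float(timepoint_h),
    )
    check_control_qc(summary)
    return summary


def check_control_qc(controls: ControlSummary) -> None:
    if not controls.gmed_neg > 0:
        raise PlateQCError(
            f"median vehicle-control growth {controls.gmed_neg:g} is not > 0"
        )
    if not controls.gmed_pos < 0:
        raise PlateQCError(
            f"median positive-control growth {controls.gmed_pos:g} is not < 0"
        )


def compute_ngr_unclipped(g_drug: float, controls: ControlSummary) -> float:
    """NGR before clipping (kept for diagnostics and the proliferative class)."""
    check_control_qc(controls)
    if g_drug > 0:
        return g_drug / controls.gmed_neg
    if g_drug < 0:
        return -(g_drug / controls.gmed_pos)
    return 0.0


def compute_ngr(g_drug: float, controls: ControlSummary) -> float:
    """Clipped normalized growth rate in [-1, 1]."""
    return float(np.clip(compute_ngr_unclipped(g_drug, controls), -1.0, 1.0))


def classify_response(ngr: float, tol: float = CLASS_TOL) -> str:
    """Qualitative class of an NGR value.

    proliferative (> 1, only meaningful pre-clip), normal (= 1), cytostatic
    ([0, 1)), cytotoxic (< 0; -1 is complete killing).
    """
    if ngr > 1.0 + tol:
        return "proliferative"
    if abs(ngr - 1.0) <= tol:
        return "normal"
    if ngr >= 0.0:
        return "cytostatic"
    return "cytotoxic"


def compute_ngr_table(
    table: ExperimentTable, timepoint_h: float | None = None
) -> pd.DataFrame:
    """NGR of every treated well at one timepoint (default: the last).

    Controls are summarized per plate and treated wells are normalized
    against their own plate's controls.  Wells with non-positive baseline
    viability are excluded with a warning.  Returns one row per treated well
    with columns: cell_line, drug, concentration_nM, replicate_id,
    timepoint_h, ngr, ngr_unclipped, response_class.
    """
    df = table.records
    if timepoint_h is None:
        timepoint_h = float(np.max(table.timepoints))
    t0 = float(np.min(table.timepoints))

    base = df[df["timepoint_h"] == t0].set_index(["plate_id", "well"])
    endp = df[df["timepoint_h"] == timepoint_h].set_index(["plate_id", "well"])
    if len(endp) == 0:
        raise MissingControlError(f"no measurements at timepoint {timepoint_h:g} h")
    common = endp.index.intersection(base.index)

    rows = []
    for plate_id, well in common:
        b = base.loc[(plate_id, well)]
        e = endp.loc[(plate_id, well)]
        v0 = float(compute_viability(b["total_area"], b["dead_area"]))
        vx = float(compute_viability(e["total_area"], e["dead_area"]))
        if v0 <= 0:
            warnings.warn(
                f"excluding degenerate well {plate_id}/{well}: baseline viability 0",
                stacklevel=2,
            )
            continue
        rows.append(
            dict(
                plate_id=plate_id,
                well=well,
                cell_line=e["cell_line"],
                drug=e["drug"],
                concentration_nM=float(e["concentration_nM"]),
                replicate_id=e["replicate_id"],
                G=compute_growth(v0, vx),
            )
        )
    growths = pd.DataFrame(rows)
    if len(growths) == 0:
        raise MissingControlError("no usable wells at the requested timepoint")

    out = []
    for plate_id, plate_df in growths.groupby("plate_id", sort=True):
        controls = summarize_controls(plate_df, timepoint_h)
        treated = plate_df[~plate_df["drug"].isin(CONTROL_DRUGS)]
        for _, row in treated.iterrows():
            raw = compute_ngr_unclipped(row["G"], controls)
            clipped = float(np.clip(raw, -1.0, 1.0))
            out.append(
                dict(
                    cell_line=row["cell_line"],
                    drug=row["drug"],
                    concentration_nM=row["concentration_nM"],
                    replicate_id=row["replicate_id"],
                    timepoint_h=timepoint_h,
                    ngr=clipped,
                    ngr_unclipped=raw,
                    response_class=classify_response(raw),
                )
            )
    result = pd.DataFrame(out)
    return result.sort_values(
        ["cell_line", "drug", "replicate_id", "concentration_nM"]
    ).reset_index(drop=True)
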