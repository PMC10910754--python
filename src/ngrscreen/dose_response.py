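"""Sigmoidal growth-rate (GR) dose-response fitting and derived metrics.

Model: GR(c) = GRinf + (1 - GRinf) / (1 + (c / GEC50)^h).  Fits run per
cell line x drug x replicate on clipped NGR values, with a single
outlier-detection pass followed by one refit.  Derived metrics are NGR50
(concentration where the fitted response crosses 0.5) and AOC (area between
y = 1 and the fitted curve over the tested log-concentration range,
normalized by its maximum attainable value 2 x log-range).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import InsufficientDataError
from .plate_io import CONTROL_DRUGS

#: Initial guesses: (GRinf, GEC50, h) = (0.1, median tested dose, 2).
P0_GRINF = 0.1
P0_HILL = 2.0

#: Outlier rule: |r| > OUTLIER_FACTOR * mean(|r|) AND |r| > OUTLIER_ABS.
OUTLIER_FACTOR = 2.5
OUTLIER_ABS = 0.25

#: Hill-coefficient bounds; GEC50 is bounded to [c_min/10, c_max*10].
HILL_MAX = 10.0

#: Minimum points retained for a reported (re)fit.
MIN_POINTS = 4

#: Default number of quadrature nodes for the AOC integral.
AOC_NODES = 513


def gr_model(c, grinf, gec50, hill):
    """Evaluate the GR equation; c may be scalar or array, in nM.

    gr_model(0) = 1 for any parameters; gr_model(GEC50) = (1 + GRinf)/2;
    gr_model(inf) = GRinf.
    """
    c = np.asarray(c, dtype=float)
    with np.errstate(over="ignore"):
        ratio = np.power(c / gec50, hill)
        out = grinf + (1.0 - grinf) / (1.0 + ratio)
    # (c/gec50)^h overflows for huge c; the limit there is GRinf exactly
    out = np.where(np.isfinite(ratio), out, grinf)
    return out if out.ndim else float(out)


@dataclass
class GRFit:
    """Fitted GR parameters with residual and outlier diagnostics."""

    grinf: float
    gec50: float
    hill: float
    residuals: np.ndarray
    outlier_flags: np.ndarray
    refitted: bool
    refit_skipped: bool
    rmse: float
    n_points: int
    converged: bool
    concentrations: np.ndarray = field(repr=False, default=None)  # type: ignore
    ngr: np.ndarray = field(repr=False, default=None)  # type: ignore

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.outlier_flags))

    def predict(self, c):
        return gr_model(c, self.grinf, self.gec50, self.hill)


def detect_outliers(residuals) -> np.ndarray:
    """Flag points whose error is both relatively and absolutely large.

    A point is an outlier iff |r| > 2.5 x mean(|r|) AND |r| > 0.25; the two
    conditions are conjunctive.
    """
    r = np.abs(np.asarray(residuals, dtype=float))
    if len(r) == 0:
        return np.zeros(0, dtype=bool)
    return (r > OUTLIER_FACTOR * r.mean()) & (r > OUTLIER_ABS)


def _curve_fit(c, y, p0, bounds):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(
            gr_model, c, y, p0=p0, bounds=bounds, maxfev=20000, method="trf"
        )
    return popt


def fit_gr(concentrations, ngr) -> GRFit:
    """Least-squares fit of the GR equation to one replicate's (c, NGR) data.

    Requires >= 5 points over >= 3 distinct concentrations.  After the first
    converged fit, the outlier rule runs exactly once; if any point is
    flagged and at least 4 points remain, the model is refit on the retained
    points.  Non-converged fits are returned flagged, never dropped.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(ngr, dtype=float)
    if len(c) != len(y):
        raise ValueError("concentrations and ngr must have equal length")
    if len(c) < 5 or len(np.unique(c)) < 3:
        raise InsufficientDataError(
            f"need >= 5 points over >= 3 distinct concentrations, "
            f"got {len(c)} points / {len(np.unique(c))} doses"
        )
    c_min, c_max = float(c.min()), float(c.max())
    p0 = (P0_GRINF, float(np.median(c)), P0_HILL)
    bounds = ([-1.0, c_min / 10.0, 1e-6], [1.0, c_max * 10.0, HILL_MAX])

    try:
        popt = _curve_fit(c, y, p0, bounds)
        converged = True
    except RuntimeError:
        popt = np.clip(p0, bounds[0], bounds[1])
        converged = False

    residuals = y - gr_model(c, *popt)
    flags = np.zeros(len(c), dtype=bool)
    refitted = False
    refit_skipped = False
    if converged:
        flags = detect_outliers(residuals)
        if flags.any():
            if len(c) - flags.sum() >= MIN_POINTS:
                try:
                    popt = _curve_fit(c[~flags], y[~flags], p0, bounds)
                    refitted = True
                    residuals = y - gr_model(c, *popt)
                except RuntimeError:
                    converged = False
            else:
                refit_skipped = True

    kept = residuals[~flags]
    rmse = float(np.sqrt(np.mean(kept**2))) if len(kept) else math.nan
    return GRFit(
        grinf=float(popt[0]),
        gec50=float(popt[1]),
        hill=float(popt[2]),
        residuals=residuals,
        outlier_flags=flags,
        refitted=refitted,
        refit_skipped=refit_skipped,
        rmse=rmse,
        n_points=len(c),
        converged=converged,
        concentrations=c,
        ngr=y,
    )


def ngr50(fit: GRFit, c_max: float) -> float:
    """Concentration where the fitted response equals 0.5, in nM.

    Closed form: c = GEC50 * ((1 - GRinf)/(0.5 - GRinf) - 1)^(1/h).  Returns
    ``math.inf`` (rendered as "> c_max") when the curve never reaches 0.5
    (GRinf >= 0.5) or the crossing lies beyond ``c_max``.
    """
    return _ngr50_params(fit.grinf, fit.gec50, fit.hill, c_max)


def _ngr50_params(grinf: float, gec50: float, hill: float, c_max: float) -> float:
    if grinf >= 0.5:
        return math.inf
    c = gec50 * ((1.0 - grinf) / (0.5 - grinf) - 1.0) ** (1.0 / hill)
    return c if c <= c_max else math.inf


def format_ngr50(value: float, c_max: float) -> str:
    return f"> {c_max:g}" if math.isinf(value) else f"{value:.6g}"


def aoc(fit: GRFit, c_min: float, c_max: float, n: int = AOC_NODES) -> float:
    """Normalized area over the fitted curve on [c_min, c_max].

    Integrates 1 - GR(10^u) over u = log10(c) by composite trapezoid on
    ``n`` log-spaced nodes, with the curve clipped to [-1, 1] inside the
    integrand, and divides by the maximum attainable area 2 x (log10 c_max -
    log10 c_min).  Result lies in [0, 1]: 0 for a drug-inert flat curve at
    1, 0.5 for pure cytostasis at 0, 1 for complete killing everywhere.
    """
    return _aoc_params(fit.grinf, fit.gec50, fit.hill, c_min, c_max, n)


def _aoc_params(grinf, gec50, hill, c_min, c_max, n: int = AOC_NODES) -> float:
    if not c_min < c_max:
        raise ValueError("require c_min < c_max")
    u = np.linspace(math.log10(c_min), math.log10(c_max), n)
    curve = np.clip(gr_model(10.0**u, grinf, gec50, hill), -1.0, 1.0)
    area = float(np.trapezoid(1.0 - curve, u))
    return area / (2.0 * (u[-1] - u[0]))


def compute_metrics(
    ngr_table: pd.DataFrame,
    culture: str = "3D",
    c_min: float | None = None,
    c_max: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit every cell line x drug x replicate and derive NGR50 and AOC.

    ``ngr_table`` is the output of :func:`ngr_core.compute_ngr_table`.
    Returns a metrics DataFrame (one row per fit) and a dict of GRFit
    objects keyed by (cell_line, drug, replicate_id).
    """
    treated = ngr_table[~ngr_table["drug"].isin(CONTROL_DRUGS)]
    if c_min is None:
        c_min = float(treated["concentration_nM"].min())
    if c_max is None:
        c_max = float(treated["concentration_nM"].max())

    rows = []
    fits: dict[tuple[str, str, str], GRFit] = {}
    for (cell_line, drug, rep), grp in treated.groupby(
        ["cell_line", "drug", "replicate_id"], sort=True
    ):
        fit = fit_gr(grp["concentration_nM"].to_numpy(), grp["ngr"].to_numpy())
        fits[(cell_line, drug, rep)] = fit
        n50 = ngr50(fit, c_max) if fit.converged else math.nan
        rows.append(
            dict(
                cell_line=cell_line,
                drug=drug,
                culture=culture,
                replicate_id=rep,
                GRinf=fit.grinf,
                GEC50_nM=fit.gec50,
                h_GR=fit.hill,
                NGR50_nM=n50,
                AOC=aoc(fit, c_min, c_max) if fit.converged else math.nan,
                rmse=fit.rmse,
                n_outliers=fit.n_outliers,
                converged=fit.converged,
            )
        )
    return pd.DataFrame(rows), fits


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of AOC per cell line x drug x culture (report layout)."""
    g = metrics.groupby(["culture", "drug", "cell_line"], sort=True)["AOC"]
    out = g.agg(AOC_mean="mean", AOC_sd="std", n="count").reset_index()
    return out
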