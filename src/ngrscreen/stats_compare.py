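"""Signed AOC fold changes and replicate-level comparison statistics.

Fold changes use the ratio-of-larger-to-smaller convention with a sign:
positive when the test AOC exceeds the reference, negative when it falls
below, so |value| >= 1 always and fold_change(a, a) = +1.

The comparison layer runs a two-way ANOVA (cell line x drug, with
interaction) on replicate AOCs and Dunnett-style contrasts of every
non-reference line against the reference within each drug, with family-wise
error controlled jointly across all contrasts at alpha via the
multivariate-t distribution of the contrast statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import (
    ConfigError,
    InsufficientReplicationError,
    UndefinedFoldChangeError,
)

#: Family-wise significance level.
ALPHA = 0.05


@dataclass(frozen=True)
class FoldChange:
    """Signed AOC ratio between a test and a reference condition."""

    reference: str
    test: str
    drug: str | None
    value: float
    direction: str  # increase | decrease | equal


@dataclass
class ComparisonResult:
    """Two-way ANOVA table plus Dunnett-adjusted contrasts vs the reference."""

    anova: pd.DataFrame
    contrasts: pd.DataFrame
    reference: str
    alpha: float
    mse: float
    df_resid: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.contrasts[self.contrasts["significant"]]


def fold_change(
    aoc_ref: float,
    aoc_test: float,
    *,
    reference: str = "reference",
    test: str = "test",
    drug: str | None = None,
    rel_tol: float = 1e-12,
) -> FoldChange:
    """Signed fold change of a test AOC against a reference AOC.

    value = +test/ref when test > ref, -ref/test when test < ref, +1 when
    equal.  Antisymmetric: swapping the arguments flips the sign.
    """
    if not (aoc_ref > 0 and aoc_test > 0):
        raise UndefinedFoldChangeError(
            f"fold change undefined for non-positive AOCs ({aoc_ref}, {aoc_test})"
        )
    if math.isclose(aoc_ref, aoc_test, rel_tol=rel_tol):
        value, direction = 1.0, "equal"
    elif aoc_test > aoc_ref:
        value, direction = aoc_test / aoc_ref, "increase"
    else:
        value, direction = -aoc_ref / aoc_test, "decrease"
    return FoldChange(
        reference=reference, test=test, drug=drug, value=value, direction=direction
    )


def fold_change_table(metrics: pd.DataFrame, reference_line: str) -> pd.DataFrame:
    """Per-drug fold change of each line's mean AOC against the reference."""
    means = metrics.groupby(["drug", "cell_line"], sort=True)["AOC"].mean()
    rows = []
    for drug in metrics["drug"].unique():
        if (drug, reference_line) not in means.index:
            raise ConfigError(f"reference line {reference_line!r} absent for {drug!r}")
        ref = means[(drug, reference_line)]
        for line in metrics.loc[metrics["drug"] == drug, "cell_line"].unique():
            if line == reference_line:
                continue
            fc = fold_change(
                ref,
                means[(drug, line)],
                reference=reference_line,
                test=line,
                drug=drug,
            )
            rows.append(
                dict(
                    drug=drug,
                    cell_line=line,
                    aoc_reference=ref,
                    aoc_test=means[(drug, line)],
                    fold_change=fc.value,
                    direction=fc.direction,
                )
            )
    return pd.DataFrame(rows)


def _contrast_correlation(n_test: np.ndarray, n_ref: np.ndarray, same_drug):
    """Correlation of contrast statistics sharing (or not) a control cell."""
    k = len(n_test)
    var = 1.0 / n_test + 1.0 / n_ref
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if same_drug[i] == same_drug[j]:
                cov = 1.0 / n_ref[i]
                corr[i, j] = corr[j, i] = cov / math.sqrt(var[i] * var[j])
    return corr


#: Monte-Carlo draws used to evaluate the multivariate-t max-|T| tail.
DUNNETT_DRAWS = 100_000


def _dunnett_adjust(t_stats, corr, df, seed=0, draws=DUNNETT_DRAWS):
    """Two-sided Dunnett adjustment from the multivariate-t max-|T| law.

    The contrast statistics share a pooled variance estimate and (within a
    drug) the reference cell mean, making them jointly multivariate t with
    correlation ``corr`` and ``df`` degrees of freedom.  The family-wise
    adjusted p of contrast i is P(max_j |T_j| >= |t_i|), evaluated by seeded
    Monte Carlo with all contrasts sharing one sample.
    """
    t_stats = np.asarray(t_stats, dtype=float)
    k = len(t_stats)
    if k == 1:
        return np.array([2.0 * stats.t.sf(abs(t_stats[0]), df)])
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((draws, k)) @ chol.T
    scale = np.sqrt(rng.chisquare(df, draws) / df)
    max_abs_t = np.max(np.abs(z), axis=1) / scale
    out = np.empty(k)
    for i, t in enumerate(np.abs(t_stats)):
        if not math.isfinite(t):
            out[i] = 0.0
            continue
        out[i] = float(np.mean(max_abs_t >= t))
    return out


def compare_aoc(
    metrics: pd.DataFrame,
    reference_line: str,
    alpha: float = ALPHA,
    seed: int = 0,
) -> ComparisonResult:
    """Two-way ANOVA on replicate AOCs with Dunnett contrasts vs reference.

    ``metrics`` needs columns cell_line, drug, replicate_id, AOC (one
    culture at a time).  Normality and homoscedasticity are assumed.
    """
    required = {"cell_line", "drug", "replicate_id", "AOC"}
    missing = required - set(metrics.columns)
    if missing:
        raise ConfigError(f"metrics table missing columns {sorted(missing)}")
    lines = metrics["cell_line"].unique()
    if reference_line not in lines:
        raise ConfigError(f"reference cell line {reference_line!r} not in metrics")
    if len(lines) < 2:
        raise ConfigError("need at least one non-reference cell line to compare")

    counts = metrics.groupby(["cell_line", "drug"])["AOC"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise InsufficientReplicationError(
            f"cells with fewer than 2 replicates: {bad}"
        )

    df = metrics.loc[:, ["cell_line", "drug", "AOC"]].copy()
    n_drugs = df["drug"].nunique()
    formula = (
        "AOC ~ C(cell_line) * C(drug)" if n_drugs > 1 else "AOC ~ C(cell_line)"
    )
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    dof = float(model.df_resid)

    cell_means = df.groupby(["drug", "cell_line"])["AOC"].mean()
    cell_n = df.groupby(["drug", "cell_line"])["AOC"].count()

    rows = []
    for drug in sorted(df["drug"].unique()):
        for line in sorted(set(df.loc[df["drug"] == drug, "cell_line"])):
            if line == reference_line:
                continue
            est = cell_means[(drug, line)] - cell_means[(drug, reference_line)]
            n_t = cell_n[(drug, line)]
            n_r = cell_n[(drug, reference_line)]
            se = math.sqrt(mse * (1.0 / n_t + 1.0 / n_r))
            if se == 0.0:
                t_stat = 0.0 if est == 0.0 else math.copysign(math.inf, est)
            else:
                t_stat = est / se
            rows.append(
                dict(
                    drug=drug,
                    cell_line=line,
                    estimate=est,
                    n_test=n_t,
                    n_ref=n_r,
                    t=t_stat,
                    p_unadjusted=float(2.0 * stats.t.sf(abs(t_stat), dof)),
                )
            )
    contrasts = pd.DataFrame(rows)
    corr = _contrast_correlation(
        contrasts["n_test"].to_numpy(float),
        contrasts["n_ref"].to_numpy(float),
        contrasts["drug"].tolist(),
    )
    contrasts["p_adjusted"] = _dunnett_adjust(
        contrasts["t"].to_numpy(float), corr, dof, seed=seed
    )
    contrasts["p_adjusted"] = np.maximum(
        contrasts["p_adjusted"], contrasts["p_unadjusted"]
    )
    contrasts["significant"] = contrasts["p_adjusted"] < alpha
    return ComparisonResult(
        anova=anova,
        contrasts=contrasts,
        reference=reference_line,
        alpha=alpha,
        mse=mse,
        df_resid=dof,
    )
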