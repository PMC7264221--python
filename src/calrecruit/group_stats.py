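"""Group comparisons: two-factor ANOVA with Bonferroni post hoc, and
proportion/contingency statistics for incidence counts.

The ANOVA uses Type II sums of squares (the experiment designs are
unbalanced, e.g. 10/10/5/5 cultures per cell) via statsmodels OLS; the
Bonferroni post hoc compares cell means with two-sample t statistics pooled
on the ANOVA error term. Normality screening is reported as a diagnostic
only and never branches the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DegenerateTableError, DesignError, ParameterError, ReferenceError_

INTERACTION = "interaction"


@dataclass
class EffectResult:
    """One ANOVA effect: F statistic, degrees of freedom, p value."""

    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition keyed by effect name."""

    factor_a: str
    factor_b: str
    effects: dict[str, EffectResult]
    mse: float       # pooled error mean square
    df_resid: int
    normality_p: float | None = None  # Shapiro p of residuals, diagnostic only

    def effect(self, name: str) -> EffectResult:
        return self.effects[name]


def _check_design(df: pd.DataFrame, response: str, factor_a: str, factor_b: str) -> None:
    for col in (response, factor_a, factor_b):
        if col not in df.columns:
            raise DesignError(f"column {col!r} missing from summary table")
    la = df[factor_a].unique()
    lb = df[factor_b].unique()
    if len(la) < 2 or len(lb) < 2:
        raise DesignError(
            f"need >= 2 levels per factor, got {len(la)} x {len(lb)}"
        )
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    missing = [
        (a, b) for a in la for b in lb if (a, b) not in counts.index
    ]
    if missing:
        raise DesignError(f"empty design cells: {missing}")


def two_way_anova(
    df: pd.DataFrame, response: str, factor_a: str, factor_b: str
) -> AnovaResult:
    """Two-factor ANOVA with interaction, Type II sums of squares.

    Returns F, degrees of freedom and p per effect (keys: the two factor
    names and ``"interaction"``). A response with zero total variance yields
    F = 0, p = 1 for every effect.
    """
    _check_design(df, response, factor_a, factor_b)
    data = df.rename(columns={response: "_y", factor_a: "_a", factor_b: "_b"})
    levels_a = data["_a"].nunique()
    levels_b = data["_b"].nunique()
    df_a, df_b = levels_a - 1, levels_b - 1
    df_ab = df_a * df_b
    df_resid = len(data) - levels_a * levels_b
    if df_resid < 1:
        raise DesignError("no residual degrees of freedom (need replication per cell)")
    y = data["_y"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        effects = {
            name: EffectResult(0.0, d, df_resid, 1.0)
            for name, d in ((factor_a, df_a), (factor_b, df_b), (INTERACTION, df_ab))
        }
        return AnovaResult(factor_a, factor_b, effects, 0.0, df_resid, None)
    model = smf.ols("_y ~ C(_a) * C(_b)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    key_map = {
        "C(_a)": factor_a,
        "C(_b)": factor_b,
        "C(_a):C(_b)": INTERACTION,
    }
    mse = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    effects = {}
    for row_key, name in key_map.items():
        F = float(table.loc[row_key, "F"])
        p = float(table.loc[row_key, "PR(>F)"])
        if not np.isfinite(F):  # zero effect SS with zero MSE
            F, p = 0.0, 1.0
        effects[name] = EffectResult(F, int(table.loc[row_key, "df"]), df_resid, p)
    try:
        norm_p = float(sps.shapiro(model.resid).pvalue) if 3 <= len(y) <= 5000 else None
    except ValueError:
        norm_p = None
    return AnovaResult(factor_a, factor_b, effects, mse, df_resid, norm_p)


def bonferroni_posthoc(
    df: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    comparisons: Sequence[tuple[tuple[str, str], tuple[str, str]]],
) -> pd.DataFrame:
    """Pairwise cell comparisons with Bonferroni-adjusted p values.

    Each comparison is a pair of (factor_a level, factor_b level) cells.
    t statistics use the pooled ANOVA error term; raw p values are
    multiplied by the number of comparisons and capped at 1.
    """
    if not comparisons:
        raise ParameterError("no comparisons requested")
    anova = two_way_anova(df, response, factor_a, factor_b)
    cells = {
        key: grp[response].to_numpy(dtype=float)
        for key, grp in df.groupby([factor_a, factor_b], observed=True)
    }
    m = len(comparisons)
    rows = []
    for cell1, cell2 in comparisons:
        for cell in (cell1, cell2):
            if tuple(cell) not in cells:
                raise ReferenceError_(f"comparison references unknown cell {cell}")
        g1, g2 = cells[tuple(cell1)], cells[tuple(cell2)]
        diff = g1.mean() - g2.mean()
        if anova.mse > 0:
            se = np.sqrt(anova.mse * (1 / len(g1) + 1 / len(g2)))
            t = diff / se
            p_raw = 2 * sps.t.sf(abs(t), anova.df_resid)
        else:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p_raw = 1.0 if diff == 0 else 0.0
        rows.append(
            {
                "cell_1": tuple(cell1),
                "cell_2": tuple(cell2),
                "mean_diff": diff,
                "t": float(t),
                "df": anova.df_resid,
                "p_raw": float(p_raw),
                "p_adjusted": float(min(1.0, m * p_raw)),
            }
        )
    return pd.DataFrame(rows)


def proportion_from_counts(events: int, total: int) -> float:
    """Percentage ``100 * events / total`` reported to one decimal place."""
    if total <= 0:
        raise ParameterError(f"total must be > 0, got {total}")
    if not (0 <= events <= total):
        raise ParameterError(f"events must be in [0, {total}], got {events}")
    return round(100.0 * events / total, 1)


@dataclass
class ContingencyTable2x2:
    """2x2 count table with optional row/column labels."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("group_1", "group_2")
    col_labels: tuple[str, str] = ("event", "no_event")

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2) or np.any(c < 0) or not np.issubdtype(c.dtype, np.number):
            raise ParameterError("counts must be a 2x2 nonnegative array")
        if c.sum() <= 0:
            raise ParameterError("table must contain at least one observation")
        self.counts = c.astype(float)


def pearson_chi2_2x2(
    table: ContingencyTable2x2 | np.ndarray, yates: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table: ``sum (O - E)^2 / E``, df = 1.

    With ``yates=True`` the Yates continuity correction
    ``(|O - E| - 0.5)^2 / E`` (floored at zero) is applied. Returns
    (statistic, df, p).
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(np.asarray(table))
    O = table.counts
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateTableError("table has a zero marginal; chi-square undefined")
    E = np.outer(row, col) / O.sum()
    dev = np.abs(O - E)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / E))
    p = float(sps.chi2.sf(stat, 1))
    return stat, 1, p
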