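"""Factorial ANOVA metamodel for the Monte Carlo outcomes.

The metamodel regresses an outcome (per-replicate weak-factor RMSD, or
per-loading ARE) on the design factors — method M, sample size N, constraint
C and factor correlation CO — including all main effects and two-way
interactions; CO terms are dropped for the one-factor model.  Because the
replication counts make even negligible effects significant, each effect is
summarized by its explained-variance share.  The effect-size statistic
reported as eta squared is the partial form SS_effect/(SS_effect + SS_error),
with the classical SS_effect/SS_total decomposition alongside and the model
R-squared as the total explained variance.  Sums of squares are Type II,
which is exact in the balanced case and stable under the mild unbalance left
by deleting improper solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass
class AnovaTable:
    """Effect decomposition of one metamodel fit."""

    table: pd.DataFrame  # effect, df, sum_sq, F, p, eta_sq (partial), eta_sq_classical
    error_df: int
    error_ms: float
    r_squared: float  # total explained variance (sum SS_effects / SS_total)
    n_obs: int

    def eta_squared(self, effect: str) -> float:
        return float(self.table.set_index("effect").loc[effect, "eta_sq"])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.loc[len(out)] = ["Error", self.error_df, self.error_ms * self.error_df,
                             np.nan, np.nan, np.nan, np.nan]
        out.loc[len(out)] = ["Total", self.n_obs - 1, np.nan, np.nan, np.nan,
                             self.r_squared, self.r_squared]
        out.to_csv(path, index=False, float_format="%.6g")


def interpret_eta2(value: float) -> str:
    """Band an eta-squared value: below 0.05 negligible, 0.05-0.09 small,
    0.10-0.20 medium, above 0.20 large."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"eta squared {value} outside [0, 1]")
    if value < 0.05:
        return "negligible"
    if value < 0.10:
        return "small"
    if value <= 0.20:
        return "medium"
    return "large"


def _effects(model_id: str, factors: list[str]) -> list[tuple[str, str]]:
    """(label, patsy term) pairs: main effects then two-way interactions."""
    columns = {"M": "M", "N": "N", "C": "Cn", "CO": "CO"}
    mains = [(label, f"C({col})") for label, col in columns.items()
             if col in factors]
    labels = [m[0] for m in mains]
    terms = dict(mains)
    inter = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            inter.append((f"{a}*{b}", f"{terms[a]}:{terms[b]}"))
    return mains + inter


def fit_metamodel(
    observations: pd.DataFrame,
    model_id: str,
    outcome: str = "rmsd_weak",
) -> AnovaTable:
    """Fit the factorial metamodel to per-replicate (or per-loading)
    observations.

    ``observations`` must carry the outcome column plus ``method``, ``N``,
    ``constraint`` and (multi-factor models) ``factor_correlation``.  Rows
    with a missing outcome (improper solutions) are dropped; design cells
    emptied entirely are dropped with a warning.
    """
    df = observations.copy()
    df = df[np.isfinite(df[outcome])]
    if len(df) < 2:
        raise ValueError("need at least two valid observations")
    df = df.rename(columns={"method": "M", "constraint": "Cn"})
    factors = ["M", "N", "Cn"]
    if model_id != "1F":
        df["CO"] = df["factor_correlation"]
        factors.append("CO")
    constant = [f for f in factors if df[f].nunique() < 2]
    if constant:
        warnings.warn(
            f"factors with a single observed level dropped: {constant}",
            stacklevel=2,
        )
        factors = [f for f in factors if f not in constant]
    if not factors:
        raise ValueError("no design factor varies in the observations")
    cell_keys = df.groupby(factors, observed=True).size()
    expected = np.prod([df[f].nunique() for f in factors])
    if len(cell_keys) < expected:
        warnings.warn(
            f"{expected - len(cell_keys)} empty design cells dropped from the "
            "metamodel; the Type II decomposition handles the unbalance",
            stacklevel=2,
        )
    if (cell_keys < 2).any():
        warnings.warn("some design cells have fewer than 2 valid observations",
                      stacklevel=2)

    effects = _effects(model_id, factors)
    formula = f"{outcome} ~ " + " + ".join(term for _, term in effects)
    ols = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # F of aliased terms
        aov = anova_lm(ols, typ=2)
    ss_error = float(aov.loc["Residual", "sum_sq"])
    df_error = int(aov.loc["Residual", "df"])
    ss_total = float(((df[outcome] - df[outcome].mean()) ** 2).sum())
    rows = []
    for label, term in effects:
        if term not in aov.index:  # pragma: no cover - aliased/empty term
            continue
        ss = float(aov.loc[term, "sum_sq"])
        rows.append(
            dict(
                effect=label,
                df=int(aov.loc[term, "df"]),
                sum_sq=ss,
                F=float(aov.loc[term, "F"]),
                p=float(aov.loc[term, "PR(>F)"]),
                eta_sq=ss / (ss + ss_error) if ss + ss_error > 0 else 0.0,
                eta_sq_classical=ss / ss_total if ss_total > 0 else 0.0,
            )
        )
    table = pd.DataFrame(rows)
    return AnovaTable(
        table=table,
        error_df=df_error,
        error_ms=ss_error / df_error,
        r_squared=float(ols.rsquared),
        n_obs=int(len(df)),
    )
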