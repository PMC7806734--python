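"""Group-level statistics: genotype x age two-way ANOVA with Fisher's LSD
post-hoc, and regressions of alternation on bidirectional-transition
predictors.

Cohorts here are unbalanced (group sizes differ by age and genotype), so the
ANOVA uses Type-III sums of squares with sum-to-zero factor coding; on a
balanced design this reproduces the classical closed-form decomposition
exactly.  Fisher's LSD is the unprotected pairwise t-test using the pooled
ANOVA error term — no multiplicity correction, by definition.

The regression convention follows the maze analyses: alternation percentage
is treated as the known variable on the x-axis and the transition predictor
as y.  R-squared of a simple OLS fit is symmetric in the two variables, so
this choice does not affect the reported R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "RegressionResult",
    "LsdResult",
    "two_way_anova",
    "fishers_lsd",
    "marginal_lsd",
    "composite_transition_score",
    "regress_alternation",
]


@dataclass(frozen=True)
class AnovaEffect:
    ss: float
    df: int
    ms: float
    f: float
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """Per-effect decomposition plus the pooled error term used by LSD."""

    factor_a: str
    factor_b: str
    effects: Mapping[str, AnovaEffect]  # keys: factor_a, factor_b, "interaction"
    mse: float
    df_error: int
    n_obs: int
    cell_means: Mapping[tuple[str, str], float]
    cell_ns: Mapping[tuple[str, str], int]

    def __str__(self) -> str:
        lines = [f"{'effect':<14}{'SS':>10}{'df':>5}{'MS':>10}{'F':>9}{'p':>10}"]
        for name, e in self.effects.items():
            lines.append(
                f"{name:<14}{e.ss:>10.3f}{e.df:>5d}{e.ms:>10.3f}{e.f:>9.3f}{e.p:>10.4f}"
            )
        lines.append(
            f"{'error':<14}{self.mse * self.df_error:>10.3f}{self.df_error:>5d}"
            f"{self.mse:>10.3f}"
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


@dataclass(frozen=True)
class LsdResult:
    t: float
    df: int
    p: float
    mean_diff: float


def two_way_anova(
    table: pd.DataFrame,
    factor_a: str,
    factor_b: str,
    value: str = "value",
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction, Type-III SS.

    ``table`` is tidy: one row per observation with categorical columns
    ``factor_a``/``factor_b`` and a numeric ``value`` column.  Requires at
    least 2 levels per factor and at least one observation per cell.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = table[[factor_a, factor_b, value]].dropna().copy()
    df.columns = ["A", "B", "y"]
    df["A"] = df["A"].astype(str)
    df["B"] = df["B"].astype(str)

    levels_a = sorted(df["A"].unique())
    levels_b = sorted(df["B"].unique())
    if len(levels_a) < 2:
        raise ValueError(f"factor {factor_a!r} has a single level")
    if len(levels_b) < 2:
        raise ValueError(f"factor {factor_b!r} has a single level")
    cell_ns: dict[tuple[str, str], int] = {}
    cell_means: dict[tuple[str, str], float] = {}
    for a in levels_a:
        for b in levels_b:
            sub = df[(df["A"] == a) & (df["B"] == b)]["y"]
            if len(sub) == 0:
                raise ValueError(f"empty cell: {factor_a}={a}, {factor_b}={b}")
            cell_ns[(a, b)] = len(sub)
            cell_means[(a, b)] = float(sub.mean())

    model = ols("y ~ C(A, Sum) * C(B, Sum)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=3)

    df_error = int(aov.loc["Residual", "df"])
    ss_error = float(aov.loc["Residual", "sum_sq"])
    if df_error < 1:
        raise ValueError("no error degrees of freedom (one observation per cell)")
    mse = ss_error / df_error
    scale = max(1.0, float(np.var(df["y"])) * len(df))
    if mse <= 1e-12 * scale:
        raise ValueError("zero error variance; F statistics undefined")

    def effect(row: str) -> AnovaEffect:
        ss = float(aov.loc[row, "sum_sq"])
        dfe = int(aov.loc[row, "df"])
        ms = ss / dfe
        f = ms / mse
        p = float(stats.f.sf(f, dfe, df_error))
        return AnovaEffect(ss=ss, df=dfe, ms=ms, f=f, p=p)

    effects = {
        factor_a: effect("C(A, Sum)"),
        factor_b: effect("C(B, Sum)"),
        "interaction": effect("C(A, Sum):C(B, Sum)"),
    }
    return AnovaResult(
        factor_a=factor_a,
        factor_b=factor_b,
        effects=effects,
        mse=mse,
        df_error=df_error,
        n_obs=len(df),
        cell_means=cell_means,
        cell_ns=cell_ns,
    )


def fishers_lsd(
    anova: AnovaResult,
    mean1: float,
    n1: int,
    mean2: float,
    n2: int,
) -> LsdResult:
    """Fisher's LSD t-test between two (cell or marginal) means.

    t = (m1 - m2) / sqrt(MSE * (1/n1 + 1/n2)) on the ANOVA error df;
    two-sided p, no multiplicity correction.
    """
    if anova.mse <= 0:
        raise ValueError("zero MSE: LSD undefined")
    diff = mean1 - mean2
    se = np.sqrt(anova.mse * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    p = 2.0 * float(stats.t.sf(abs(t), anova.df_error))
    return LsdResult(t=float(t), df=anova.df_error, p=p, mean_diff=float(diff))


def marginal_lsd(
    anova: AnovaResult,
    table: pd.DataFrame,
    factor: str,
    level1: str,
    level2: str,
    value: str = "value",
) -> LsdResult:
    """LSD comparison of two marginal levels of one factor."""
    g = table.groupby(table[factor].astype(str))[value]
    means, ns = g.mean(), g.size()
    return fishers_lsd(
        anova,
        float(means[level1]), int(ns[level1]),
        float(means[level2]), int(ns[level2]),
    )


def composite_transition_score(
    bi_percent: Mapping[frozenset[str], float],
    positive_pairs: Iterable[frozenset[str] | tuple[str, str]],
    negative_pairs: Iterable[frozenset[str] | tuple[str, str]] = (),
) -> float:
    """Signed sum of bidirectional transition percentages.

    score = sum over positive pairs of bi% - sum over negative pairs of bi%.
    The positive and negative sets must be disjoint.
    """
    pos = {frozenset(p) for p in positive_pairs}
    neg = {frozenset(p) for p in negative_pairs}
    if pos & neg:
        raise ValueError(f"overlapping pair sets: {sorted(map(sorted, pos & neg))}")
    return sum(bi_percent[p] for p in pos) - sum(bi_percent[p] for p in neg)


def regress_alternation(
    alternation_values: Sequence[float],
    predictor_values: Sequence[float],
) -> RegressionResult:
    """Simple OLS of a transition predictor on alternation percentage.

    Alternation is the x variable, the predictor y (the maze convention);
    R^2 and the slope-t p-value are identical under the swapped convention.
    """
    x = np.asarray(alternation_values, dtype=float)
    y = np.asarray(predictor_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("alternation and predictor must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p=float(fit.pvalue),
        n=len(x),
    )
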