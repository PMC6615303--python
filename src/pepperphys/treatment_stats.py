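"""Factorial statistics for the salinity x leaching-fraction design.

Two-way fixed-effects ANOVA on the balanced complete design (where
Type I and Type III sums of squares coincide), Duncan's multiple range
test for post-hoc letter displays, an ANCOVA slope-homogeneity test for
the P_n ~ ln(g_s) relationship, and plain OLS regression.  Model fitting
is delegated to statsmodels; Duncan's procedure is implemented here from
the studentized-range distribution because no installed package provides
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as scipy_stats
from scipy.stats import linregress, studentized_range
from statsmodels.stats.anova import anova_lm


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition: one row per term plus the residual."""

    table: pd.DataFrame  # index: term; columns: sum_sq, df, F, p
    residual_df: float
    residual_ms: float

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass
class MrtGrouping:
    """Duncan letter display: levels sharing a letter do not differ at alpha."""

    levels: list
    means: np.ndarray  # sorted descending
    letters: list[str]  # parallel to levels/means
    alpha: float


@dataclass
class AncovaResult:
    """Slope-homogeneity test of a covariate across groups."""

    group_slopes: dict
    common_slope: float
    interaction_f: float
    interaction_p: float
    interaction_df: tuple
    covariate: str = "ln_gs"


def significance_stars(p: float) -> str:
    """Conventional star codes: *** p<0.001, ** p<0.01, * p<0.05, else NS."""
    if np.isnan(p):
        return "NS"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def _check_balanced(df: pd.DataFrame, a: str, b: str) -> int:
    counts = df.groupby([a, b]).size()
    full = df[a].nunique() * df[b].nunique()
    if len(counts) < full:
        raise ValueError("design has empty cells; only complete designs are supported")
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: cell counts differ "
            f"({counts.min()}..{counts.max()}); this analysis is balanced-only"
        )
    return int(counts.iloc[0])


def two_way_anova(response, factor_a, factor_b, names=("A", "B")) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction on a balanced design.

    ``response`` is numeric; ``factor_a``/``factor_b`` are level labels of
    equal length.  Returns sums of squares, F and p per term; a constant
    response yields zero sums of squares and undefined (NaN) F ratios.
    """
    df = pd.DataFrame(
        {"y": np.asarray(response, dtype=float), "fa": list(factor_a), "fb": list(factor_b)}
    )
    n_per_cell = _check_balanced(df, "fa", "fb")
    if n_per_cell < 2:
        raise ValueError("need >= 2 replicates per cell to estimate the residual")
    fit = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    # balanced: Type I == Type II == Type III
    tab = anova_lm(fit, typ=2)
    resid = tab.loc["Residual"]
    table = tab.drop(index="Residual").rename(
        index={
            "C(fa)": names[0],
            "C(fb)": names[1],
            "C(fa):C(fb)": f"{names[0]} x {names[1]}",
        },
        columns={"PR(>F)": "p"},
    )
    table = table[["sum_sq", "df", "F", "p"]]
    residual_ms = float(resid["sum_sq"] / resid["df"]) if resid["df"] > 0 else float("nan")
    return AnovaResult(table=table, residual_df=float(resid["df"]), residual_ms=residual_ms)


def duncan_mrt(
    means: dict, ms_error: float, df_error: float, n_per_group: int, alpha: float = 0.05
) -> MrtGrouping:
    """Duncan's multiple range test with a compact letter display.

    Means are ordered descending; the shortest significant range for a
    span of p means uses the studentized-range quantile at Duncan's
    protection level alpha_p = 1 - (1-alpha)^(p-1):

        R_p = q(1 - alpha_p; p, df_error) * sqrt(MS_error / n)

    A range of means is non-significant if its extremes differ by at most
    R_p or if it is contained in a longer non-significant range.  Levels
    spanned by a common maximal non-significant range share a letter.
    """
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive (equal group sizes required)")
    if ms_error < 0:
        raise ValueError("ms_error must be >= 0")

    levels = list(means.keys())
    m = np.array([float(means[k]) for k in levels])
    order = np.argsort(-m, kind="stable")
    levels = [levels[i] for i in order]
    m = m[order]
    k = len(levels)
    if k == 1:
        return MrtGrouping(levels=levels, means=m, letters=["a"], alpha=alpha)

    se = np.sqrt(ms_error / n_per_group)
    crit = {
        p: studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df_error) * se
        for p in range(2, k + 1)
    }

    nonsig = np.zeros((k, k), dtype=bool)  # nonsig[i, j], i < j in sorted order
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if m[i] - m[j] <= crit[span] or _contained_nonsig(nonsig, i, j):
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        nonsig[a, b] = True

    letters = _compact_letter_display(nonsig, k)
    return MrtGrouping(levels=levels, means=m, letters=letters, alpha=alpha)


def _contained_nonsig(nonsig: np.ndarray, i: int, j: int) -> bool:
    # Duncan protection: a range inside an already-accepted homogeneous
    # range is never declared significant.  Containment in sorted order
    # means some accepted (a, b) with a <= i and j <= b.
    k = nonsig.shape[0]
    for a in range(0, i + 1):
        for b in range(j, k):
            if (a, b) != (i, j) and nonsig[a, b] and (b - a) > (j - i):
                return True
    return False


def _compact_letter_display(nonsig: np.ndarray, k: int) -> list[str]:
    # maximal homogeneous intervals -> one letter each (nonsignificance is
    # interval-closed by construction)
    intervals = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        if not intervals or intervals[-1][1] < j:
            intervals.append((i, j))
        i += 1
    # drop intervals nested in others
    maximal = [
        (a, b)
        for (a, b) in intervals
        if not any((c <= a and b <= d) and (c, d) != (a, b) for (c, d) in intervals)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for letter_idx, (a, b) in enumerate(sorted(maximal)):
        for pos in range(a, b + 1):
            letters[pos] += alphabet[letter_idx]
    return letters


def ancova_slope_test(pn, gs, group_labels, alpha: float = 0.05) -> AncovaResult:
    """Test whether the slope of P_n on ln(g_s) differs across groups.

    Fits P_n ~ group + ln(g_s) + group:ln(g_s) and reports the interaction
    F test; the common slope comes from the additive model (the standard
    follow-up when slopes are homogeneous) and per-group slopes from
    separate OLS fits.
    """
    df = pd.DataFrame(
        {
            "pn": np.asarray(pn, dtype=float),
            "gs": np.asarray(gs, dtype=float),
            "group": list(group_labels),
        }
    )
    if np.any(df["gs"] <= 0):
        raise ValueError("stomatal conductance must be > 0")
    counts = df.groupby("group").size()
    if np.any(counts < 3):
        raise ValueError("need at least 3 observations per group")
    df["ln_gs"] = np.log(df["gs"])
    if df.groupby("group")["ln_gs"].nunique().min() < 2:
        raise ValueError("singular design: a group has no ln(g_s) variance")

    full = smf.ols("pn ~ C(group) * ln_gs", data=df).fit()
    reduced = smf.ols("pn ~ C(group) + ln_gs", data=df).fit()
    # extra-sum-of-squares F; clamped so an exact fit (both RSS ~ 0 to
    # round-off) reports a zero interaction rather than noise
    df_num = float(reduced.df_resid - full.df_resid)
    df_den = float(full.df_resid)
    ss_diff = max(float(reduced.ssr - full.ssr), 0.0)
    tol = 1e-10 * max(float(np.sum(df["pn"] ** 2)), 1.0)
    if ss_diff <= tol:
        ss_diff = 0.0
    if full.ssr <= tol:
        f_stat = 0.0 if ss_diff == 0.0 else float("inf")
    else:
        f_stat = (ss_diff / df_num) / (full.ssr / df_den)
    p_val = float(scipy_stats.f.sf(f_stat, df_num, df_den)) if np.isfinite(f_stat) else 0.0

    slopes = {}
    for g, sub in df.groupby("group"):
        res = linregress(sub["ln_gs"], sub["pn"])
        slopes[g] = float(res.slope)
    return AncovaResult(
        group_slopes=slopes,
        common_slope=float(reduced.params["ln_gs"]),
        interaction_f=f_stat,
        interaction_p=p_val,
        interaction_df=(df_num, df_den),
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_stderr: float = float("nan")


def linear_regression_r2(x, y) -> RegressionResult:
    """Simple OLS of y on x with R^2 and the two-sided slope t-test."""
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x_arr) == 0:
        raise ValueError("x has zero variance")
    res = linregress(x_arr, y_arr)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x_arr.size),
        slope_stderr=float(res.stderr),
    )
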