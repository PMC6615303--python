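"""Derived leaf gas-exchange metrics.

Intrinsic water-use efficiency is the ratio of net photosynthesis to
stomatal conductance, P_n / g_s (umol CO2 mol^-1 H2O); C_i/C_a is the
intercellular-to-ambient CO2 mole-fraction ratio, a proxy for stomatal
limitation.  Treatment summaries expose both aggregation orders for WUE
— mean of per-observation ratios and ratio of treatment means — because
the two differ whenever P_n/g_s covaries with g_s, as it strongly does
under partial stomatal closure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def intrinsic_wue(pn, gs):
    """Per-observation intrinsic WUE, P_n / g_s (umol CO2 mol^-1 H2O)."""
    pn_arr = np.asarray(pn, dtype=float)
    gs_arr = np.asarray(gs, dtype=float)
    if np.any(gs_arr <= 0):
        raise ValueError("stomatal conductance must be > 0")
    out = pn_arr / gs_arr
    return float(out) if out.ndim == 0 else out


def ci_ca_ratio(ci, ca):
    """Intercellular-to-ambient CO2 ratio C_i / C_a (dimensionless)."""
    ci_arr = np.asarray(ci, dtype=float)
    ca_arr = np.asarray(ca, dtype=float)
    if np.any(ca_arr <= 0):
        raise ValueError("ambient CO2 must be > 0")
    return float(ci_arr / ca_arr) if ci_arr.ndim == 0 and ca_arr.ndim == 0 else ci_arr / ca_arr


def percent_reduction(reference, treatment, ndigits: int | None = None):
    """Percent reduction of ``treatment`` relative to ``reference``.

    (reference - treatment) / reference * 100; pass ``ndigits`` to round
    for reporting (tables conventionally use one decimal).
    """
    ref = np.asarray(reference, dtype=float)
    trt = np.asarray(treatment, dtype=float)
    if np.any(ref == 0):
        raise ValueError("reference must be nonzero")
    out = (ref - trt) / ref * 100.0
    if ndigits is not None:
        out = np.round(out, ndigits)
    return float(out) if out.ndim == 0 else out


def fit_pn_gs_log(pn, gs):
    """OLS fit of the logarithmic link P_n = a + b*ln(g_s).

    Returns (a, b, r_squared, n).  Stomatal closure produces this shape
    because assimilation saturates while conductance keeps falling.
    """
    pn_arr = np.asarray(pn, dtype=float)
    gs_arr = np.asarray(gs, dtype=float)
    if pn_arr.size < 3:
        raise ValueError("need at least 3 observations")
    if np.any(gs_arr <= 0):
        raise ValueError("stomatal conductance must be > 0")
    x = np.log(gs_arr)
    if np.ptp(x) == 0:
        raise ValueError("singular design: ln(g_s) has no variance")
    res = stats.linregress(x, pn_arr)
    return float(res.intercept), float(res.slope), float(res.rvalue**2), int(pn_arr.size)


def treatment_summary(
    obs: pd.DataFrame, by, average_days_first: bool = True
) -> pd.DataFrame:
    """Treatment-level gas-exchange means with both WUE aggregations.

    ``obs`` needs columns pn, gs, ci, ca (and pot_id/day when
    ``average_days_first``, which first averages repeated measurement
    days within each pot so each pot contributes one replicate).
    Output columns: pn, gs, ci_ca, wue_mean_of_ratios (per-observation
    P_n/g_s averaged), wue_ratio_of_means (mean P_n over mean g_s), n.
    """
    work = obs.copy()
    work["ci_ca"] = ci_ca_ratio(work["ci"], work["ca"])
    work["wue"] = intrinsic_wue(work["pn"], work["gs"])
    if isinstance(by, str):
        by = [by]
    if average_days_first and "pot_id" in work.columns:
        work = work.groupby(list(by) + ["pot_id"], as_index=False)[
            ["pn", "gs", "ci_ca", "wue"]
        ].mean()
    grouped = work.groupby(list(by))
    out = grouped[["pn", "gs", "ci_ca", "wue"]].mean()
    out = out.rename(columns={"wue": "wue_mean_of_ratios"})
    out["wue_ratio_of_means"] = grouped["pn"].mean() / grouped["gs"].mean()
    out["n"] = grouped.size()
    return out.reset_index()
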