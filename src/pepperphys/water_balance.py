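"""Pot water balance, leaching-fraction scheduling and seasonal accounting.

Each pot is weighed just before every irrigation.  Between irrigation n
and n+1 the evapotranspiration (g) is

    ET = W_n - W_{n+1} + (AW - D) * rho

with pot weights W (g), applied water AW and drainage D (L), and water
bulk density rho (g L^-1, default 1000).  The irrigation scheduler uses
the leaching relation AW / ET = 1 / (1 - LF): to maintain a target
leaching fraction LF the pot receives AW = ET / (rho * (1 - LF)).  A
``paper_multiplier`` mode instead applies the factor 1/(1 - LF) rounded
to one decimal (1.2 for LF 0.17, 1.4 for LF 0.29), the rounded-percentage
convention often used in practice; the small gap between the two modes is
one reason seasonal *actual* leaching fractions drift below their target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RHO_DEFAULT = 1000.0  # g per litre


@dataclass(frozen=True)
class LeachingTarget:
    """Target leaching fraction: drainage volume / applied volume."""

    lf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lf < 1.0:
            raise ValueError(f"leaching fraction must be in [0, 1), got {self.lf}")


def compute_et(w_before, w_next, applied_water, drainage, rho: float = RHO_DEFAULT):
    """Evapotranspiration (g) over one inter-irrigation interval.

    ``w_before`` and ``w_next`` are pot weights (g) just before this and
    the next irrigation; ``applied_water`` and ``drainage`` are in litres.
    Negative results are physically suspect (weighing noise) and are
    flagged with a warning, not clipped.
    """
    wb = np.asarray(w_before, dtype=float)
    wn = np.asarray(w_next, dtype=float)
    aw = np.asarray(applied_water, dtype=float)
    d = np.asarray(drainage, dtype=float)
    if np.any(wb <= 0) or np.any(wn <= 0):
        raise ValueError("pot weights must be positive")
    if np.any(aw < 0):
        raise ValueError("applied water must be >= 0")
    if np.any(d < 0) or np.any(d > aw):
        raise ValueError("drainage must satisfy 0 <= D <= AW")
    if rho <= 0:
        raise ValueError("rho must be positive")
    et = wb - wn + (aw - d) * rho
    if np.any(et < 0):
        warnings.warn("negative ET computed; check weighing records", stacklevel=2)
    return float(et) if et.ndim == 0 else et


def required_applied_water(
    et, target: LeachingTarget | float, rho: float = RHO_DEFAULT, mode: str = "exact"
):
    """Applied water (L) needed to hold a target leaching fraction.

    ``mode='exact'`` uses AW = (ET/rho) / (1 - LF); ``mode='paper_multiplier'``
    applies the one-decimal rounding of 1/(1 - LF) (e.g. 120% / 140% of ET
    for LF targets 0.17 / 0.29).
    """
    lf = target.lf if isinstance(target, LeachingTarget) else LeachingTarget(float(target)).lf
    et_arr = np.asarray(et, dtype=float)
    if np.any(et_arr < 0):
        raise ValueError("ET must be >= 0")
    if mode == "exact":
        factor = 1.0 / (1.0 - lf)
    elif mode == "paper_multiplier":
        factor = round(1.0 / (1.0 - lf), 1)
    else:
        raise ValueError(f"unknown scheduler mode {mode!r}")
    out = et_arr / rho * factor
    return float(out) if out.ndim == 0 else out


def implied_lf(applied_water, et, rho: float = RHO_DEFAULT):
    """Leaching fraction implied by applied water and ET: LF = 1 - (ET/rho)/AW.

    Negative values (applied water below ET) are clipped to 0 with a warning.
    """
    aw = np.asarray(applied_water, dtype=float)
    et_arr = np.asarray(et, dtype=float)
    if np.any(aw <= 0):
        raise ValueError("applied water must be > 0")
    if np.any(et_arr < 0):
        raise ValueError("ET must be >= 0")
    lf = 1.0 - et_arr / rho / aw
    if np.any(lf < 0):
        warnings.warn("applied water below ET implies negative LF; clipping to 0", stacklevel=2)
        lf = np.maximum(lf, 0.0)
    return float(lf) if lf.ndim == 0 else lf


def seasonal_actual_lf(ledger: pd.DataFrame, by: str = "pot_id") -> pd.Series:
    """Seasonal actual leaching fraction per pot: sum(D) / sum(AW).

    ``ledger`` needs columns ``applied_L`` and ``drainage_L`` plus the
    grouping column (default ``pot_id``).
    """
    required = {by, "applied_L", "drainage_L"}
    missing = required - set(ledger.columns)
    if missing:
        raise KeyError(f"ledger missing columns: {sorted(missing)}")
    grouped = ledger.groupby(by, sort=True)
    totals = grouped[["applied_L", "drainage_L"]].sum()
    if np.any(totals["applied_L"] <= 0):
        raise ValueError("total applied water must be positive for every pot")
    return (totals["drainage_L"] / totals["applied_L"]).rename("actual_lf")


def season_summary(ledger: pd.DataFrame, units: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-pot seasonal water accounting, optionally joined to treatment labels.

    Returns one row per pot with total ET (g), applied water and drainage
    (L), and the seasonal actual leaching fraction; if ``units`` with
    ``pot_id``/``ec_iw``/``target_lf`` columns is given, treatment labels
    are merged in so callers can aggregate by treatment.
    """
    et = compute_et(
        ledger["w_before_g"], ledger["w_next_g"], ledger["applied_L"], ledger["drainage_L"]
    )
    work = ledger.assign(et_g=et)
    out = (
        work.groupby("pot_id", sort=True)
        .agg(
            n_events=("event_index", "size"),
            total_et_g=("et_g", "sum"),
            total_applied_L=("applied_L", "sum"),
            total_drainage_L=("drainage_L", "sum"),
        )
        .reset_index()
    )
    out["actual_lf"] = out["total_drainage_L"] / out["total_applied_L"]
    if units is not None:
        out = out.merge(units[["pot_id", "ec_iw", "target_lf"]], on="pot_id", how="left")
    return out
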