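"""Stable-isotope compositions and discrimination for leaf dry matter.

delta13C is expressed per mil against the PDB (Pee Dee Belemnite)
13C/12C standard; delta15N against atmospheric N2, whose 15N abundance
is 0.3663 atom % (stored here as the fraction 0.003663).  Carbon isotope
discrimination Delta13C relates plant material (delta_p) to source air
(delta_a, default -8 per mil):

    Delta = (delta_a - delta_p) / (1 + delta_p)

with the deltas as *fractions*; the formula is dimensionally meaningless
with per-mil values in the denominator, so inputs are converted to
fractions internally and the result is returned per mil.  Total element
accumulation is content (% of dry weight) times dry biomass.
"""

from __future__ import annotations

import numpy as np

#: 15N/(14N+15N) of atmospheric N2 as a fraction (0.3663 atom %).
R_B_15N = 0.003663

#: Carbon isotope composition of source air, per mil vs PDB.
DELTA_A_DEFAULT = -8.0


def _as_positive(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError(f"{name} must be > 0")
    return arr


def delta13c(r_sample, r_standard) -> float | np.ndarray:
    """delta13C (per mil) from sample and PDB-standard 13C/12C ratios."""
    rs = _as_positive(r_sample, "r_sample")
    rstd = _as_positive(r_standard, "r_standard")
    out = (rs / rstd - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def delta15n(r_s, r_b=R_B_15N, *, r_b_in_atom_percent: bool = False) -> float | np.ndarray:
    """delta15N (per mil) from sample and standard 15N abundance ratios.

    ``r_b`` defaults to the atmospheric fraction 0.003663; pass
    ``r_b_in_atom_percent=True`` if the standard is supplied in atom %
    (e.g. 0.3663).
    """
    if r_b_in_atom_percent:
        r_b = np.asarray(r_b, dtype=float) / 100.0
    rs = _as_positive(r_s, "r_s")
    rb = _as_positive(r_b, "r_b")
    out = (rs / rb - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def big_delta13c(delta_p, delta_a=DELTA_A_DEFAULT) -> float | np.ndarray:
    """Carbon isotope discrimination Delta13C (per mil).

    Parameters are per mil; computation is carried out in fractional
    units, Delta = (da - dp) / (1 + dp), and rescaled to per mil.
    """
    dp = np.asarray(delta_p, dtype=float)
    da = np.asarray(delta_a, dtype=float)
    if np.any(dp <= -1000.0):
        raise ValueError("delta_p must exceed -1000 per mil (denominator would vanish)")
    out = (da / 1000.0 - dp / 1000.0) / (1.0 + dp / 1000.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def invert_big_delta13c(big_delta, delta_a=DELTA_A_DEFAULT) -> float | np.ndarray:
    """Plant delta13C (per mil) producing a given discrimination.

    Exact algebraic inverse of :func:`big_delta13c`:
    dp = (da - Delta) / (1 + Delta) in fractional units.
    """
    d = np.asarray(big_delta, dtype=float) / 1000.0
    da = np.asarray(delta_a, dtype=float) / 1000.0
    out = (da - d) / (1.0 + d) * 1000.0
    return float(out) if out.ndim == 0 else out


def total_accumulation(content_percent, dry_biomass) -> float | np.ndarray:
    """Total element accumulation (g plant^-1) from content (% DW) and biomass (g)."""
    c = np.asarray(content_percent, dtype=float)
    b = np.asarray(dry_biomass, dtype=float)
    if np.any(c < 0) or np.any(c > 100):
        raise ValueError("content_percent must lie in [0, 100]")
    if np.any(b < 0):
        raise ValueError("dry_biomass must be >= 0")
    out = c / 100.0 * b
    return float(out) if out.ndim == 0 else out
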