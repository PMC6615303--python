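"""Photosynthetic light-response and CO2-response curve models.

The light response of net photosynthesis ``P_n`` to photon flux density
``Q`` (PPFD) is modelled as a non-rectangular hyperbola,

    P_n(Q) = [a*Q + Pmax - sqrt((a*Q + Pmax)^2 - 4*k*a*Q*Pmax)] / (2*k) - Rd,

where ``a`` (alpha) is the maximum apparent quantum yield of CO2
(mol CO2 mol^-1 photons), ``Pmax`` the irradiance-saturated gross rate
(umol CO2 m^-2 s^-1), ``k`` (kappa) a dimensionless convexity in [0, 1]
interpolating between a rectangular hyperbola (k -> 0) and a Blackman
two-line response (k = 1), and ``Rd`` the dark respiration rate.

The response to intercellular CO2 ``C_i`` is a rectangular hyperbola
offset by photorespiration,

    P_n(C_i) = eps*Psat*C_i / (eps*C_i + Psat) - Rp,

with carboxylation efficiency ``eps`` (initial slope, mol m^-2 s^-1),
photosynthetic capacity ``Psat`` (umol CO2 m^-2 s^-1) and
photorespiration rate ``Rp``.

Both models are fitted by bounded nonlinear least squares
(:func:`scipy.optimize.least_squares`) with data-driven initial values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


class FitError(ValueError):
    """Raised when a curve fit cannot be attempted or is degenerate."""


@dataclass(frozen=True)
class LightResponseParams:
    """Parameters of the non-rectangular hyperbola light-response model."""

    alpha: float  # maximum apparent quantum yield (mol CO2 mol^-1 photons)
    pn_max: float  # irradiance-saturated gross photosynthesis (umol m^-2 s^-1)
    kappa: float  # dimensionless convexity, in [0, 1]
    rd: float  # dark respiration rate (umol CO2 m^-2 s^-1)

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.pn_max > 0:
            raise ValueError(f"pn_max must be > 0, got {self.pn_max}")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        if self.rd < 0:
            raise ValueError(f"rd must be >= 0, got {self.rd}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.pn_max, self.kappa, self.rd])


@dataclass(frozen=True)
class CO2ResponseParams:
    """Parameters of the CO2-response model."""

    epsilon: float  # carboxylation efficiency (mol m^-2 s^-1)
    pn_sat: float  # photosynthetic capacity (umol CO2 m^-2 s^-1)
    rp: float  # photorespiration rate (umol CO2 m^-2 s^-1)

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if not self.pn_sat > 0:
            raise ValueError(f"pn_sat must be > 0, got {self.pn_sat}")
        if self.rp < 0:
            raise ValueError(f"rp must be >= 0, got {self.rp}")

    def as_array(self) -> np.ndarray:
        return np.array([self.epsilon, self.pn_sat, self.rp])


@dataclass
class CurveFitResult:
    """Outcome of a bounded least-squares curve fit."""

    params: LightResponseParams | CO2ResponseParams
    rss: float
    r_squared: float
    converged: bool
    n_points: int
    stderr: np.ndarray = field(default_factory=lambda: np.array([]))


def _gross_nrh(q: np.ndarray, alpha: float, pn_max: float, kappa: float) -> np.ndarray:
    """Gross non-rectangular-hyperbola rate via the conjugate (stable) form.

    The textbook expression divides the smaller quadratic root by 2*kappa,
    which cancels catastrophically for small kappa and is singular at
    kappa = 0.  Multiplying through by the conjugate gives

        gross = 2*alpha*Q*Pmax / [(alpha*Q + Pmax) + sqrt((alpha*Q + Pmax)^2
                                                  - 4*kappa*alpha*Q*Pmax)]

    which is finite and continuous for kappa in [0, 1], and reduces to the
    rectangular hyperbola alpha*Q*Pmax/(alpha*Q + Pmax) at kappa = 0.
    """
    s = alpha * q + pn_max
    disc = s * s - 4.0 * kappa * alpha * q * pn_max
    # clip tiny negative round-off at kappa = 1 where disc is a perfect square
    disc = np.maximum(disc, 0.0)
    return 2.0 * alpha * q * pn_max / (s + np.sqrt(disc))


def eval_light_response(params: LightResponseParams, q) -> np.ndarray | float:
    """Net photosynthesis rate at PPFD ``q`` (umol photons m^-2 s^-1).

    ``q`` may be a scalar or array; negative irradiance raises ValueError.
    """
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0):
        raise ValueError("PPFD must be non-negative")
    out = _gross_nrh(q_arr, params.alpha, params.pn_max, params.kappa) - params.rd
    return float(out) if np.isscalar(q) or q_arr.ndim == 0 else out


def eval_co2_response(params: CO2ResponseParams, ci) -> np.ndarray | float:
    """Net photosynthesis rate at intercellular CO2 ``ci`` (umol mol^-1)."""
    ci_arr = np.asarray(ci, dtype=float)
    if np.any(ci_arr < 0):
        raise ValueError("C_i must be non-negative")
    out = (
        params.epsilon * params.pn_sat * ci_arr / (params.epsilon * ci_arr + params.pn_sat)
        - params.rp
    )
    return float(out) if np.isscalar(ci) or ci_arr.ndim == 0 else out


def co2_compensation_point(params: CO2ResponseParams) -> float:
    """C_i at which the CO2-response model crosses zero net assimilation.

    Solving eps*Psat*Ci/(eps*Ci + Psat) = Rp gives
    Ci* = Rp*Psat / (eps*(Psat - Rp)); the curve never reaches zero when
    its plateau Psat - Rp is not positive.
    """
    if params.pn_sat <= params.rp:
        raise ValueError(
            "compensation point undefined: pn_sat must exceed rp "
            f"(pn_sat={params.pn_sat}, rp={params.rp})"
        )
    return params.rp * params.pn_sat / (params.epsilon * (params.pn_sat - params.rp))


# ---------------------------------------------------------------------------
# fitting

_FTOL = 1e-12
_XTOL = 1e-12
_GTOL = 1e-12
_MAX_NFEV = 500


def _check_inputs(x, y, n_min: int, label: str):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError(f"{label}: setpoints and responses must be equal-length 1-d arrays")
    if x.size < n_min:
        raise FitError(f"{label}: need at least {n_min} points, got {x.size}")
    if np.unique(x).size < n_min:
        raise FitError(f"{label}: setpoints must include at least {n_min} distinct values")
    if np.ptp(y) == 0.0:
        raise FitError(f"{label}: response is constant; curve parameters are unidentifiable")
    return x, y


def _finish(residual_fun, res, make_params, y) -> CurveFitResult:
    rss = float(2.0 * res.cost)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    n, p = y.size, res.x.size
    stderr = np.full(p, np.nan)
    if n > p:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * rss / (n - p)
            stderr = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            pass
    return CurveFitResult(
        params=make_params(res.x),
        rss=rss,
        r_squared=r2,
        converged=bool(res.success),
        n_points=int(n),
        stderr=stderr,
    )


def fit_light_response(q_values, pn_values, *, x0=None, bounds=None) -> CurveFitResult:
    """Fit the light-response model to (PPFD, P_n) points.

    Initial values: alpha from an OLS slope over the three lowest nonzero
    irradiances, Rd from the measured dark point (or the OLS intercept),
    Pmax from the highest observed rate plus Rd, kappa = 0.8.  Bounds keep
    kappa in [0, 1] and the remaining parameters positive with loose upper
    limits scaled from the data.
    """
    q, pn = _check_inputs(q_values, pn_values, 5, "light-response fit")

    if x0 is None:
        order = np.argsort(q)
        qs, ps = q[order], pn[order]
        low = np.flatnonzero(qs > 0)[:3]
        if low.size >= 2:
            slope, intercept = np.polyfit(qs[low], ps[low], 1)
        else:  # pragma: no cover - guarded by distinct-setpoint check
            slope, intercept = 0.05, ps[0]
        if qs[0] == 0:
            rd0 = max(-ps[0], 1e-3)
        else:
            rd0 = max(-intercept, 1e-3)
        alpha0 = np.clip(slope, 1e-4, 1.0)
        pnmax0 = max(pn.max() + rd0, 1e-2)
        x0 = np.array([alpha0, pnmax0, 0.8, rd0])

    if bounds is None:
        scale = max(pn.max(), 1.0)
        bounds = (
            np.array([1e-6, 1e-6, 0.0, 0.0]),
            np.array([10.0, 10.0 * (scale + x0[3]), 1.0, 10.0 * (abs(pn.min()) + 1.0)]),
        )

    def resid(theta):
        a, pmax, k, rd = theta
        return _gross_nrh(q, a, pmax, k) - rd - pn

    res = least_squares(
        resid, x0, bounds=bounds, ftol=_FTOL, xtol=_XTOL, gtol=_GTOL, max_nfev=_MAX_NFEV
    )
    return _finish(
        resid,
        res,
        lambda x: LightResponseParams(
            alpha=float(x[0]),
            pn_max=float(x[1]),
            kappa=float(min(max(x[2], 0.0), 1.0)),
            rd=float(max(x[3], 0.0)),
        ),
        pn,
    )


def fit_co2_response(ci_values, pn_values, *, x0=None, bounds=None) -> CurveFitResult:
    """Fit the CO2-response model to (C_i, P_n) points.

    Initial values mirror :func:`fit_light_response`: epsilon from an OLS
    slope over the three lowest C_i values, Rp from the implied intercept,
    Psat from the maximum rate plus Rp.
    """
    ci, pn = _check_inputs(ci_values, pn_values, 4, "CO2-response fit")

    if x0 is None:
        order = np.argsort(ci)
        cs, ps = ci[order], pn[order]
        slope, intercept = np.polyfit(cs[:3], ps[:3], 1)
        rp0 = max(-intercept, 1e-3)
        eps0 = np.clip(slope, 1e-5, 10.0)
        psat0 = max(pn.max() + rp0, 1e-2)
        x0 = np.array([eps0, psat0, rp0])

    if bounds is None:
        scale = max(pn.max(), 1.0)
        bounds = (
            np.array([1e-8, 1e-6, 0.0]),
            np.array([100.0, 10.0 * (scale + x0[2]), 10.0 * (abs(pn.min()) + 1.0)]),
        )

    def resid(theta):
        eps, psat, rp = theta
        return eps * psat * ci / (eps * ci + psat) - rp - pn

    res = least_squares(
        resid, x0, bounds=bounds, ftol=_FTOL, xtol=_XTOL, gtol=_GTOL, max_nfev=_MAX_NFEV
    )
    return _finish(
        resid,
        res,
        lambda x: CO2ResponseParams(
            epsilon=float(x[0]), pn_sat=float(x[1]), rp=float(max(x[2], 0.0))
        ),
        pn,
    )


def eval_light_response_literal(params: LightResponseParams, q) -> np.ndarray | float:
    """Literal quadratic-root form of the light-response model.

    Divides the smaller root by 2*kappa exactly as usually printed; it is
    singular at kappa = 0 and ill-conditioned nearby.  Kept only as an
    independent cross-check of the stable conjugate form.
    """
    if params.kappa == 0:
        raise ZeroDivisionError("literal form is singular at kappa = 0")
    q_arr = np.asarray(q, dtype=float)
    s = params.alpha * q_arr + params.pn_max
    disc = np.maximum(s * s - 4.0 * params.kappa * params.alpha * q_arr * params.pn_max, 0.0)
    out = (s - np.sqrt(disc)) / (2.0 * params.kappa) - params.rd
    return float(out) if np.isscalar(q) or q_arr.ndim == 0 else out
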