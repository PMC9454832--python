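"""Gas-production kinetics: sigmoidal and exponential models.

Two candidate curves describe cumulative gas Y(t) (mL STP per g DM):

* Groot sigmoidal   Y(t) = A / (1 + (B/t)^C)
  with asymptote A, half-time B (the time at which Y = A/2) and shape C
  governing steepness; for C > 1 the curve has an inflection at
  t* = B·((C−1)/(C+1))^(1/C), the time of maximum production rate.

* Exponential, no intercept   Y(t) = b·(1 − e^(−c·t))
  with asymptote b and fractional rate c (per hour); its rate is maximal
  at t = 0 where dY/dt = b·c.

Both are fitted by nonlinear least squares with parameters kept positive
via a log transform, and compared with the least-squares Akaike
information criterion AIC = n·ln(RSS/n) + 2k, where k counts the curve
parameters plus the residual-variance parameter.  The model with the
smaller AIC is selected.

Derived quantities reported per bottle: A1 (fitted curve maximum), H1
(time to half of A1, hours), Vmax (maximum rate, mL/g/h internally) and
Tmax (time of maximum rate, minutes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, SelectionError, ValidationError

GROOT = "groot"
EXPONENTIAL = "exponential"

#: Relative parameter-change tolerance at which fits are declared converged.
XTOL = 1e-10
MAX_ITER = 500


def groot_curve(t, A: float, B: float, C: float):
    """Evaluate the sigmoidal model; Y(0) = 0 by continuity (C > 0)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape, dtype=float)
    pos = t > 0
    out[pos] = A / (1.0 + (B / t[pos]) ** C)
    if out.ndim == 0:
        return float(out)
    return out


def groot_rate(t, A: float, B: float, C: float):
    """Analytic derivative dY/dt = A·C·B^C·t^(C−1) / (B^C + t^C)²."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = A * C * B**C * tp ** (C - 1.0) / (B**C + tp**C) ** 2
    if out.ndim == 0:
        return float(out)
    return out


def exponential_curve(t, b: float, c: float):
    t = np.asarray(t, dtype=float)
    out = b * (1.0 - np.exp(-c * t))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class KineticFit:
    """Result of fitting one model family to one bottle's gas curve."""

    family: str
    params: tuple[float, ...]
    rss: float
    n_obs: int
    aic: float
    converged: bool
    message: str = ""

    def predict(self, t):
        if self.family == GROOT:
            return groot_curve(t, *self.params)
        return exponential_curve(t, *self.params)

    def rate(self, t):
        if self.family == GROOT:
            return groot_rate(t, *self.params)
        b, c = self.params
        return b * c * np.exp(-c * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class DerivedKinetics:
    """Interpretable kinetics summary of a fitted curve."""

    A1_ml_per_g: float
    H1_h: float
    Vmax_ml_per_g_h: float
    Tmax_min: float

    @property
    def Vmax_ml_per_g_min(self) -> float:
        """Per-minute display of the maximum rate."""
        return self.Vmax_ml_per_g_h / 60.0


def aic_least_squares(rss: float, n: int, n_params: int) -> float:
    """Gaussian-likelihood AIC for a least-squares fit.

    k counts the curve parameters plus the residual variance.
    """
    k = n_params + 1
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def _prepare(times_h, gas_values, min_points: int):
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(gas_values, dtype=float)
    if t.shape != y.shape:
        raise FitError("times and values differ in length")
    if t.size < min_points:
        raise FitError(f"need at least {min_points} observations, got {t.size}")
    if not np.any(t > 0):
        raise FitError("need at least one observation at t > 0")
    if np.allclose(y, 0.0):
        raise FitError("degenerate data: response is identically zero")
    return t, y


def _fit(family: str, model, t, y, p0) -> KineticFit:
    """Least squares in log-parameter space (keeps all parameters > 0)."""
    lp0 = np.log(np.asarray(p0, dtype=float))

    def residuals(lp):
        return model(t, *np.exp(lp)) - y

    degenerate = np.ptp(y) < 1e-12 * max(1.0, abs(float(y[0])))
    res = least_squares(
        residuals, lp0, method="lm", xtol=XTOL, ftol=1e-12, gtol=1e-12,
        max_nfev=MAX_ITER * lp0.size,
    )
    params = tuple(float(p) for p in np.exp(res.x))
    rss = float(np.sum(res.fun**2))
    converged = bool(res.success) and np.all(np.isfinite(params)) and not degenerate
    message = "" if converged else (res.message if res.success else res.message)
    if degenerate:
        message = "degenerate data: constant response"
    return KineticFit(
        family=family,
        params=params,
        rss=rss,
        n_obs=t.size,
        aic=aic_least_squares(rss, t.size, len(params)),
        converged=converged,
        message=message,
    )


def fit_groot(times_h, gas_values) -> KineticFit:
    """Fit the sigmoidal model.

    Starting values: A₀ = max(y); B₀ = first positive time at which the
    response reaches A₀/2 (falls back to the median time when it never
    does); C₀ = 1.5.
    """
    t, y = _prepare(times_h, gas_values, min_points=4)
    A0 = float(np.max(y))
    above = (y >= A0 / 2.0) & (t > 0)
    B0 = float(t[above][0]) if above.any() else float(np.median(t[t > 0]))
    return _fit(GROOT, groot_curve, t, y, (A0, B0, 1.5))


def fit_exponential(times_h, gas_values) -> KineticFit:
    """Fit the no-intercept exponential model (b₀ = max(y), c₀ = 0.1/h)."""
    t, y = _prepare(times_h, gas_values, min_points=4)
    b0 = float(np.max(y))
    return _fit(EXPONENTIAL, exponential_curve, t, y, (b0, 0.1))


def select_model(fits: Sequence[KineticFit]) -> KineticFit:
    """Return the converged fit with least AIC."""
    candidates = [f for f in fits if f.converged]
    if not candidates:
        raise SelectionError("no converged fit to select from")
    return min(candidates, key=lambda f: f.aic)


def derive_kinetics(fit: KineticFit, first_time_h: float = 1.0 / 6.0) -> DerivedKinetics:
    """Compute A1, H1, Vmax and Tmax from a converged fit.

    For the sigmoidal family with C ≤ 1 the rate is monotonically
    decreasing, so Tmax is reported as 0 and Vmax as the rate at the first
    recording grid point (``first_time_h``, default one 10-min interval).
    """
    if not fit.converged:
        raise FitError("cannot derive kinetics from a non-converged fit")
    if fit.family == GROOT:
        A, B, C = fit.params
        if C <= 0:
            raise ValidationError("shape parameter C must be positive")
        if C > 1:
            tmax_h = B * ((C - 1.0) / (C + 1.0)) ** (1.0 / C)
            vmax = groot_rate(tmax_h, A, B, C)
        else:
            tmax_h = 0.0
            vmax = groot_rate(first_time_h, A, B, C)
        return DerivedKinetics(
            A1_ml_per_g=A,
            H1_h=B,
            Vmax_ml_per_g_h=float(vmax),
            Tmax_min=tmax_h * 60.0,
        )
    b, c = fit.params
    return DerivedKinetics(
        A1_ml_per_g=b,
        H1_h=float(np.log(2.0) / c),
        Vmax_ml_per_g_h=b * c,
        Tmax_min=0.0,
    )


def fit_bottle(times_h, gas_values,
               families: tuple[str, ...] = (GROOT, EXPONENTIAL)) -> KineticFit:
    """Fit all requested families to one curve and select by least AIC."""
    fitters = {GROOT: fit_groot, EXPONENTIAL: fit_exponential}
    fits = [fitters[f](times_h, gas_values) for f in families]
    return select_model(fits)
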