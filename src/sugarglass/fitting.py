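"""Curve models for the water-content analysis of sugar glasses.

Three least-squares fits:

* Gordon–Taylor mixing rule for the glass transition of a binary
  trehalose–water system,
      Tg(x_t) = (x_t·Tg_t + k1·(1−x_t)·Tg_w) / (x_t + k1·(1−x_t)),
  with the pure-component Tg values fixed and k1 fitted.

* The same functional form reused for the trehalose–trehalose H-bond
  stoichiometry N(x_t) (bonds per participating molecule), with the dry
  value N_pure fixed and (k2, N_inf) fitted; N_inf is the
  infinite-dilution stoichiometry.

* A four-parameter Gaussian for normalized post-rehydration viability,
      y(x) = y0 + A·exp(−(x−xc)²/(2w²)),
  from which EC50 — the water content where viability crosses 0.5 on
  the low-water (descending) branch — is extracted by root finding.

Nonlinear fits run a deterministic multi-start grid (no randomness) and
report R².  Composition may be given either as trehalose mass fraction
x_t or water content R (gH2O/gdw); the two are linked by x_t = 1/(1+R).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares


class FitError(RuntimeError):
    """Raised when a fit cannot converge or its preconditions fail."""


def x_t_from_content(water_content: np.ndarray | float) -> np.ndarray | float:
    """Trehalose mass fraction from water content R (gH2O/gdw)."""
    r = np.asarray(water_content, dtype=float)
    if np.any(r < 0):
        raise ValueError("water content must be non-negative")
    out = 1.0 / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def content_from_x_t(x_t: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x_t, dtype=float)
    if np.any((x <= 0) | (x > 1)):
        raise ValueError("mass fraction must be in (0, 1]")
    out = 1.0 / x - 1.0
    return float(out) if out.ndim == 0 else out


# ------------------------------------------------------------- predictions

def gt_predict(x_t, tg_t: float, tg_w: float, k1: float):
    """Gordon–Taylor Tg of the mixture, in K."""
    if k1 <= 0:
        raise ValueError("k1 must be positive")
    x = np.asarray(x_t, dtype=float)
    out = (x * tg_t + k1 * (1.0 - x) * tg_w) / (x + k1 * (1.0 - x))
    return float(out) if out.ndim == 0 else out


def mgt_predict(x_t, n_pure: float, n_inf: float, k2: float):
    """Gordon–Taylor-form H-bond stoichiometry, bonds per bonded molecule."""
    x = np.asarray(x_t, dtype=float)
    out = (x * n_pure + k2 * (1.0 - x) * n_inf) / (x + k2 * (1.0 - x))
    return float(out) if out.ndim == 0 else out


def gaussian_predict(x, y0: float, a: float, xc: float, w: float):
    """Gaussian viability curve; peak y0+a at xc, baseline y0 far away."""
    if w <= 0:
        raise ValueError("w must be positive")
    xx = np.asarray(x, dtype=float)
    out = y0 + a * np.exp(-((xx - xc) ** 2) / (2.0 * w**2))
    return float(out) if out.ndim == 0 else out


# -------------------------------------------------------------- fit results

@dataclass(frozen=True)
class GordonTaylorFit:
    tg_t: float
    tg_w: float
    k1: float
    r2: float
    flags: tuple[str, ...] = ()

    def predict(self, x_t):
        return gt_predict(x_t, self.tg_t, self.tg_w, self.k1)


@dataclass(frozen=True)
class ModifiedGTFit:
    n_pure: float
    n_inf: float
    k2: float
    r2: float
    flags: tuple[str, ...] = ()

    def predict(self, x_t):
        return mgt_predict(x_t, self.n_pure, self.n_inf, self.k2)


@dataclass(frozen=True)
class ViabilityFit:
    y0: float
    a: float
    xc: float
    w: float
    r2: float
    flags: tuple[str, ...] = ()

    def predict(self, x):
        return gaussian_predict(x, self.y0, self.a, self.xc, self.w)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def _prepare_xy(
    x: Sequence[float],
    y: Sequence[float],
    weights: Sequence[float] | None,
    x_is_content: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    xt = x_t_from_content(x) if x_is_content else x
    if np.any((xt < 0) | (xt > 1)):
        raise ValueError("mass fractions must lie in [0, 1]")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    return np.atleast_1d(xt), np.atleast_1d(y), np.atleast_1d(w)


# --------------------------------------------------------------------- fits

def fit_gordon_taylor(
    x: Sequence[float],
    tg: Sequence[float],
    tg_t: float,
    tg_w: float,
    weights: Sequence[float] | None = None,
    x_is_content: bool = False,
) -> GordonTaylorFit:
    """Fit k1 with the pure-component glass transitions fixed."""
    xt, y, w = _prepare_xy(x, tg, weights, x_is_content)
    interior = (xt > 0) & (xt < 1)
    if np.unique(xt[interior]).size < 1 or xt.size < 2:
        raise FitError("need at least two points with an interior composition")

    def resid(theta):
        return (gt_predict(xt, tg_t, tg_w, np.exp(theta[0])) - y) * w

    best = None
    for k0 in (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0):
        sol = least_squares(resid, x0=[np.log(k0)], method="lm", xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("Gordon-Taylor fit did not converge from any start")
    k1 = float(np.exp(best.x[0]))
    yhat = gt_predict(xt, tg_t, tg_w, k1)
    return GordonTaylorFit(tg_t=tg_t, tg_w=tg_w, k1=k1, r2=_r2(y, yhat))


def fit_modified_gt(
    x: Sequence[float],
    n: Sequence[float],
    n_pure: float,
    weights: Sequence[float] | None = None,
    x_is_content: bool = False,
) -> ModifiedGTFit:
    """Fit (k2, N_inf) with the dry-glass stoichiometry N_pure fixed.

    Internally the abscissa is always the mass fraction x_t, removing the
    log-scale distortion of water-content display axes.  A warning flag
    is set when the data are flat (k2 unidentifiable) or when N_inf < 1.
    """
    xt, y, w = _prepare_xy(x, n, weights, x_is_content)
    if xt.size < 3:
        raise FitError("need at least three points to fit (k2, N_inf)")
    flags: list[str] = []
    if np.allclose(y, y[0], atol=1e-12):
        flags.append("degenerate: constant data, k2 unidentifiable")
        return ModifiedGTFit(
            n_pure=n_pure, n_inf=float(y[0]), k2=1.0, r2=1.0, flags=tuple(flags)
        )

    def resid(theta):
        k2 = np.exp(theta[0])
        return (mgt_predict(xt, n_pure, theta[1], k2) - y) * w

    best = None
    n_inf_starts = (1.0, max(float(np.min(y)), 1e-6))
    for k0 in (0.3, 1.0, 3.0, 10.0):
        for ninf0 in n_inf_starts:
            sol = least_squares(
                resid, x0=[np.log(k0), ninf0], method="lm", xtol=1e-14, ftol=1e-14
            )
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success:
        raise FitError("modified Gordon-Taylor fit did not converge from any start")
    k2 = float(np.exp(best.x[0]))
    n_inf = float(best.x[1])
    if n_inf < 1.0:
        flags.append("N_inf < 1: below the single-shared-bond limit")
        warnings.warn(flags[-1], stacklevel=2)
    yhat = mgt_predict(xt, n_pure, n_inf, k2)
    return ModifiedGTFit(
        n_pure=n_pure, n_inf=n_inf, k2=k2, r2=_r2(y, yhat), flags=tuple(flags)
    )


def fit_viability(
    x: Sequence[float],
    viability: Sequence[float],
    weights: Sequence[float] | None = None,
) -> ViabilityFit:
    """Four-parameter Gaussian fit of normalized viability vs water content."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(viability, dtype=float))
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 5:
        raise FitError("need at least five points for the four-parameter fit")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    flags: list[str] = []
    span = float(np.ptp(x))
    if np.allclose(y, y[0], atol=1e-12):
        flags.append("degenerate: flat data, amplitude unidentifiable")
        return ViabilityFit(
            y0=float(y[0]), a=0.0, xc=float(np.mean(x)), w=span / 2 or 1.0,
            r2=1.0, flags=tuple(flags),
        )

    y0_0 = float(np.min(y))
    a_0 = float(np.max(y) - np.min(y))
    xc_0 = float(x[np.argmax(y)])
    w_0 = span / 2.0

    def resid(theta):
        y0, a, xc, lw = theta
        return (gaussian_predict(x, y0, a, xc, np.exp(lw)) - y) * w

    best = None
    for fw in (0.5, 1.0, 2.0):
        for fxc in (0.75, 1.0, 1.5):
            sol = least_squares(
                resid,
                x0=[y0_0, a_0, xc_0 * fxc, np.log(max(w_0 * fw, 1e-6))],
                method="lm", xtol=1e-14, ftol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success:
        raise FitError("viability fit did not converge from any start")
    y0, a, xc, lw = best.x
    wfit = float(np.exp(lw))
    dx = np.min(np.diff(np.sort(np.unique(x)))) if np.unique(x).size > 1 else span
    if wfit < dx:
        flags.append("w collapsed below the x resolution")
        warnings.warn(flags[-1], stacklevel=2)
    yhat = gaussian_predict(x, y0, a, xc, wfit)
    return ViabilityFit(
        y0=float(y0), a=float(a), xc=float(xc), w=wfit,
        r2=_r2(y, yhat), flags=tuple(flags),
    )


def ec50(
    fit: ViabilityFit,
    search_range: tuple[float, float] | None = None,
    level: float = 0.5,
) -> float:
    """Water content where the fitted curve crosses ``level`` below xc.

    Restricted to the descending low-water branch (x < xc), matching the
    interpretation of EC50 as the water content at 50 % cell death.
    """
    lo = search_range[0] if search_range else fit.xc - 10.0 * fit.w
    hi = min(search_range[1], fit.xc) if search_range else fit.xc

    def f(x):
        return fit.predict(x) - level

    # bracket scan from xc downward
    grid = np.linspace(hi, lo, 512)
    vals = f(grid)
    idx = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if idx.size == 0:
        raise FitError(
            f"EC50 undefined for this fit: no {level} crossing in "
            f"[{lo:.4g}, {hi:.4g}] below xc"
        )
    a, b = grid[idx[0] + 1], grid[idx[0]]
    return float(brentq(f, a, b, xtol=1e-10))


def ec50_closed_form(y0: float, a: float, xc: float, w: float, level: float = 0.5) -> float:
    """Analytic low-branch crossing, defined when y0 <= level <= y0+a."""
    if not (min(y0, y0 + a) < level < max(y0, y0 + a)):
        raise ValueError("level outside the curve's range")
    return xc - w * np.sqrt(2.0 * np.log(a / (level - y0)))
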