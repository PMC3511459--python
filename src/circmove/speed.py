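"""Speed auto-regression coupled to the direction of heading.

    v_t = a*v_{t-1} + b*cos(theta_t - c) + d*cos(theta_t - theta_{t-1})
          + c0 + eta_t,          eta_t ~ N(0, sigma^2) i.i.d.

The anisotropy term ``b*cos(theta_t - c)`` makes speed largest when heading
in direction ``c`` — for a bird flying in wind, ``c`` estimates the leeward
direction.  Fitting is Gaussian conditional maximum likelihood (conditional
on the first heading and speed), equivalent to least squares once ``(b, c)``
is reparameterised as ``(b*cos c, b*sin c)``; the identifiability constraint
``b > 0`` is restored on conversion.  The untruncated Gaussian is used for
fitting; simulation redraws non-positive speeds, which in a fast cruising
regime (mean speed >> sigma) almost never triggers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import List, Optional, Tuple

import numpy as np

from .circular import wrap
from .trajectory import StepSeries

__all__ = ["SpeedParams", "SpeedModelSpec", "SpeedFitResult", "predict_speed",
           "fit_speed", "select_speed_model", "simulate_speed"]


@dataclass(frozen=True)
class SpeedParams:
    """Coefficients of the speed auto-regression (m/s units; sigma2 (m/s)^2).

    Covariates absent from a model carry coefficient 0 (and b = 0 leaves the
    leeward direction c undefined at 0).
    """

    a: float = 0.0        # previous-speed coefficient
    b: float = 0.0        # heading-anisotropy amplitude, >= 0
    c: float = 0.0        # speed-maximising heading (leeward direction)
    d: float = 0.0        # angular-velocity (turn-cosine) coefficient
    c0: float = 0.0       # intercept
    sigma2: float = 1.0   # innovation variance

    def __post_init__(self):
        if self.b < 0:
            raise ValueError("b must be non-negative (aliasing removed via c)")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        object.__setattr__(self, "c", wrap(self.c))


@dataclass(frozen=True)
class SpeedModelSpec:
    """Which covariates enter; the intercept is always present.  The
    anisotropy term contributes two parameters (b and c)."""

    previous_speed: bool = True
    heading_anisotropy: bool = True
    angular_velocity: bool = True

    @property
    def n_params(self) -> int:
        # regression coefficients + sigma^2
        return (1 + self.previous_speed + 2 * self.heading_anisotropy
                + self.angular_velocity + 1)

    def label(self) -> str:
        parts = ["1"]
        if self.previous_speed:
            parts.append("v_prev")
        if self.heading_anisotropy:
            parts.append("cos(theta-c)")
        if self.angular_velocity:
            parts.append("cos(dtheta)")
        return "+".join(parts)


@dataclass(frozen=True)
class SpeedFitResult:
    spec: SpeedModelSpec
    params: SpeedParams
    loglik: float
    aic: float
    n_steps: int
    stderr: Optional[dict] = None


def predict_speed(v_prev, theta_t, theta_prev, p: SpeedParams):
    """Conditional mean of v_t; as a function of theta_t alone it peaks at
    theta_t = c."""
    return (p.a * np.asarray(v_prev, dtype=float)
            + p.b * np.cos(np.asarray(theta_t) - p.c)
            + p.d * np.cos(np.asarray(theta_t) - np.asarray(theta_prev))
            + p.c0)


def _design(series: StepSeries, spec: SpeedModelSpec):
    v = np.asarray(series.speeds, dtype=float)
    th = np.asarray(series.headings, dtype=float)
    if np.any(~np.isfinite(th)):
        raise ValueError("series contains undefined headings")
    yv = v[1:]
    cols = [np.ones_like(yv)]
    names = ["c0"]
    if spec.previous_speed:
        cols.append(v[:-1])
        names.append("a")
    if spec.heading_anisotropy:
        cols.append(np.cos(th[1:]))
        cols.append(np.sin(th[1:]))
        names += ["b_cos", "b_sin"]
    if spec.angular_velocity:
        cols.append(np.cos(th[1:] - th[:-1]))
        names.append("d")
    return np.column_stack(cols), yv, names


def fit_speed(series: StepSeries, spec: SpeedModelSpec = SpeedModelSpec()) -> SpeedFitResult:
    """Conditional Gaussian ML fit (ordinary least squares in the
    ``(b cos c, b sin c)`` reparameterisation; ``sigma2`` is the mean squared
    residual).  AIC counts ``sigma2`` as a parameter."""
    if series.n_steps < 10:
        raise ValueError("series too short to fit (need >= 10 steps)")
    X, yv, names = _design(series, spec)
    n = yv.size
    coef, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design for speed model {spec.label()}")
    resid = yv - X @ coef
    sigma2 = float(np.mean(resid ** 2))
    if sigma2 <= 0:
        sigma2 = 1e-12
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    d = dict(zip(names, coef))
    b = c = 0.0
    if spec.heading_anisotropy:
        b = float(np.hypot(d["b_cos"], d["b_sin"]))
        c = float(np.arctan2(d["b_sin"], d["b_cos"]))
    params = SpeedParams(a=float(d.get("a", 0.0)), b=b, c=c,
                         d=float(d.get("d", 0.0)), c0=float(d["c0"]),
                         sigma2=sigma2)
    k = spec.n_params
    aic = -2.0 * loglik + 2.0 * k
    # classical OLS standard errors on the linear coefficients
    try:
        cov = sigma2 * np.linalg.inv(X.T @ X) * n / max(n - X.shape[1], 1)
        stderr = dict(zip(names, np.sqrt(np.diag(cov))))
    except np.linalg.LinAlgError:
        stderr = None
    return SpeedFitResult(spec, params, float(loglik), float(aic), n, stderr)


def select_speed_model(series: StepSeries) -> List[SpeedFitResult]:
    """Fit all 8 covariate subsets and rank by AIC (ties: fewer params)."""
    fits = []
    for pv, ha, av in product([False, True], repeat=3):
        spec = SpeedModelSpec(previous_speed=pv, heading_anisotropy=ha,
                              angular_velocity=av)
        try:
            fits.append(fit_speed(series, spec))
        except ValueError:
            continue
    if not fits:
        raise ValueError("no speed model could be fitted")
    return sorted(fits, key=lambda f: (f.aic, f.spec.n_params))


def simulate_speed(theta_seq, v0: float, p: SpeedParams, seed,
                   max_redraws: int = 1000) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate speeds along a heading sequence, redrawing non-positive
    values (truncation applied at simulation time only).

    Parameters
    ----------
    theta_seq : sequence of float
        Headings theta_0..theta_n; speeds are produced for steps 1..n.
    v0 : float
        Speed of step 0 (must be positive).

    Returns
    -------
    speeds : ndarray, shape (n,)
    redraws : ndarray of int, shape (n,)
        Number of rejected (non-positive) draws at each step.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    th = np.asarray(theta_seq, dtype=float)
    n = th.size - 1
    speeds = np.empty(n)
    redraws = np.zeros(n, dtype=int)
    sd = np.sqrt(p.sigma2)
    v_prev = float(v0)
    for t in range(n):
        mean = predict_speed(v_prev, th[t + 1], th[t], p)
        v = mean + sd * rng.standard_normal()
        k = 0
        while v <= 0:
            k += 1
            if k > max_redraws:
                raise RuntimeError(
                    "degenerate speed regime: >1000 consecutive non-positive draws")
            v = mean + sd * rng.standard_normal()
        speeds[t] = v
        redraws[t] = k
        v_prev = v
    return speeds, redraws
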