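"""Trajectory simulation and the synthetic flight scenarios.

Positions are accumulated from headings and speeds,
``x_{t+1} = x_t + T * v_t * (cos theta_t, sin theta_t)``, with headings drawn
from a heading model (Kato-Jones noise realised by transforming a von Mises
draw) and speeds from the speed auto-regression (non-positive draws
rejected).  The named scenarios emulate the flight regimes the model family
is meant to cover — steadily oriented flight, wind-skewed flight, zigzag
(reciprocating) flight, tortuous searching, and homing toward a fixed point
— with documented true parameters so estimation can be validated end-to-end
without any field data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .circular import (
    VonMisesParams,
    WrappedCauchyParams,
    sample_vm,
    sample_wc,
    wrap,
)
from .heading import (
    Family,
    FocalPoint,
    HeadingModelSpec,
    HeadingParams,
    Noise,
    step_mean,
)
from .speed import SpeedParams, predict_speed
from .trajectory import Trajectory

__all__ = ["Scenario", "simulate_trajectory", "simulate_heading_series",
           "simulate_batch", "make_fixture", "FIXTURE_KINDS"]


@dataclass(frozen=True)
class Scenario:
    """A fully parameterised simulation: heading model + speed model + start."""

    name: str
    heading_spec: HeadingModelSpec
    heading_params: HeadingParams
    speed_params: Optional[SpeedParams]   # None -> constant speed v0
    x0: float = 0.0
    y0: float = 0.0
    theta0: float = 0.0
    v0: float = 1.0
    n_steps: int = 500
    time_unit: float = 1.0
    seed: int = 0


def _draw_errors(noise: Noise, params: HeadingParams, n: int, rng) -> np.ndarray:
    """Pre-draw the i.i.d. circular innovations of a heading series."""
    if noise in (Noise.VM, Noise.KJ):
        return sample_vm(VonMisesParams(0.0, params.kappa), n, rng)
    return sample_wc(WrappedCauchyParams(0.0, params.r), n, rng)


def _apply_noise(mu, noise: Noise, params: HeadingParams, e):
    """theta_t from its conditional mean and an innovation: additive for
    symmetric noise, the generating transform (attract toward nu_t, rotate by
    mu_t) for Kato-Jones noise."""
    if noise is not Noise.KJ:
        return wrap(mu + e)
    nu = wrap(params.lambda_ - mu)
    omega = (1.0 - params.r) / (1.0 + params.r)
    u = wrap(e - nu)
    return wrap(mu + nu + 2.0 * np.arctan(omega * np.tan(0.5 * u)))


def simulate_heading_series(spec: HeadingModelSpec, params: HeadingParams,
                            theta0: float, n_steps: int, n_series: int,
                            seed) -> np.ndarray:
    """Simulate ``n_series`` heading series of ``n_steps`` steps, all starting
    from ``theta0``.  Returns shape ``(n_series, n_steps + 1)`` including the
    initial heading.  Focal-point specs need positions; use
    :func:`simulate_trajectory` for those."""
    if spec.needs_locations:
        raise ValueError("focal-point models must be simulated as trajectories")
    params = params.resolved(spec)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    e = _draw_errors(spec.noise, params, n_series * n_steps, rng).reshape(
        n_series, n_steps)
    out = np.empty((n_series, n_steps + 1))
    out[:, 0] = wrap(theta0)
    for t in range(n_steps):
        mu = step_mean(out[:, t], spec, params)
        out[:, t + 1] = _apply_noise(mu, spec.noise, params, e[:, t])
    return out


def simulate_trajectory(scenario: Scenario, seed=None) -> Trajectory:
    """Simulate one trajectory of ``n_steps`` steps (``n_steps + 1`` fixes).

    The first step uses the given initial heading and speed; subsequent
    headings come from the heading model (for focal-point models the
    attraction target is recomputed from the current position each step) and
    speeds from the speed model, redrawn while non-positive.  Bit-reproducible
    given the scenario seed.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    spec = sc.heading_spec
    params = sc.heading_params.resolved(spec)
    n = sc.n_steps
    e = _draw_errors(spec.noise, params, max(n - 1, 1), rng)
    sd = np.sqrt(sc.speed_params.sigma2) if sc.speed_params is not None else 0.0

    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    xs[0], ys[0] = sc.x0, sc.y0
    theta = wrap(sc.theta0)
    v = float(sc.v0)
    if v <= 0:
        raise ValueError("v0 must be positive")
    for t in range(n):
        if t > 0:
            mu = step_mean(theta, spec, params,
                           current_location=(xs[t], ys[t]) if spec.needs_locations else None)
            theta_new = float(_apply_noise(mu, spec.noise, params, e[t - 1]))
            if sc.speed_params is not None:
                mean = float(predict_speed(v, theta_new, theta, sc.speed_params))
                vnew = mean + sd * rng.standard_normal()
                k = 0
                while vnew <= 0:
                    k += 1
                    if k > 1000:
                        raise RuntimeError("degenerate speed regime in simulation")
                    vnew = mean + sd * rng.standard_normal()
                v = vnew
            theta = theta_new
        xs[t + 1] = xs[t] + sc.time_unit * v * np.cos(theta)
        ys[t + 1] = ys[t] + sc.time_unit * v * np.sin(theta)
    times = sc.time_unit * np.arange(n + 1)
    return Trajectory(times, xs, ys, label=sc.name)


def simulate_batch(scenario: Scenario, n_sim: int, seed=None):
    """Simulate ``n_sim`` trajectories at once (vectorised across replicas).

    Returns ``(headings, speeds, endpoints)`` with shapes ``(n_sim, n_steps)``,
    ``(n_sim, n_steps)`` and ``(n_sim, 2)``.  Column 0 holds the shared
    initial heading/speed.  Used by the goodness-of-fit machinery, where
    hundreds of replicate trajectories are needed; equivalent in law to
    repeated :func:`simulate_trajectory` runs.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    spec = sc.heading_spec
    params = sc.heading_params.resolved(spec)
    n = sc.n_steps
    if sc.v0 <= 0:
        raise ValueError("v0 must be positive")
    e = _draw_errors(spec.noise, params, n_sim * max(n - 1, 1), rng).reshape(
        n_sim, -1)
    sd = np.sqrt(sc.speed_params.sigma2) if sc.speed_params is not None else 0.0

    thetas = np.empty((n_sim, n))
    speeds = np.empty((n_sim, n))
    thetas[:, 0] = wrap(sc.theta0)
    speeds[:, 0] = sc.v0
    x = np.full(n_sim, float(sc.x0))
    y = np.full(n_sim, float(sc.y0))
    for t in range(n):
        if t > 0:
            if spec.needs_locations:
                fp = spec.constraint
                alpha_t = np.arctan2(fp.y - y, fp.x - x)
                u = wrap(thetas[:, t - 1] - alpha_t)
                mu = wrap(alpha_t + 2.0 * np.arctan(params.w * np.tan(0.5 * u)))
            else:
                mu = step_mean(thetas[:, t - 1], spec, params)
            thetas[:, t] = _apply_noise(mu, spec.noise, params, e[:, t - 1])
            if sc.speed_params is not None:
                mean = predict_speed(speeds[:, t - 1], thetas[:, t],
                                     thetas[:, t - 1], sc.speed_params)
                v = mean + sd * rng.standard_normal(n_sim)
                bad = v <= 0
                tries = 0
                while np.any(bad):
                    tries += 1
                    if tries > 1000:
                        raise RuntimeError("degenerate speed regime in simulation")
                    v[bad] = mean[bad] + sd * rng.standard_normal(int(bad.sum()))
                    bad = v <= 0
                speeds[:, t] = v
            else:
                speeds[:, t] = speeds[:, t - 1]
        x += sc.time_unit * speeds[:, t] * np.cos(thetas[:, t])
        y += sc.time_unit * speeds[:, t] * np.sin(thetas[:, t])
    return thetas, speeds, np.column_stack([x, y])


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("oriented", "wind_skewed", "zigzag", "tortuous_loop", "homing")

_CRUISE_SPEED = SpeedParams(a=0.3, b=1.5, c=5 * np.pi / 8, d=0.3, c0=6.0,
                            sigma2=0.64)


def make_fixture(kind: str, seed: int = 0, n_steps: int = 2000) -> Scenario:
    """A fully parameterised named scenario with documented true parameters.

    oriented       steady eastward flight: C-AR(VM), alpha=0, w=0.5, kappa=6.
    wind_skewed    focal direction ESE under wind toward NNW: C-AR(KJ),
                   alpha=-pi/8, w=0.7, kappa=6, r=0.3, lambda=5pi/8.
    zigzag         reciprocating headings about east: C-AR(VM) with w=-0.5.
    tortuous_loop  weakly oriented, tortuous searching with strong skew:
                   C-AR(KJ), alpha=3pi/4, w=0.85, kappa=4, r=0.5, lambda=-pi/2.
    homing         attraction toward a fixed point 30 km north: C-AR(KJ) with
                   a focal point instead of a focal direction.

    All scenarios share a cruising speed model (mean speed near 9 m/s, sigma
    0.8 m/s) so simulated speeds are essentially always positive.
    """
    base = dict(speed_params=_CRUISE_SPEED, v0=9.0, n_steps=n_steps,
                time_unit=1.0, seed=seed)
    if kind == "oriented":
        return Scenario(
            name="oriented",
            heading_spec=HeadingModelSpec(Family.CAR, Noise.VM),
            heading_params=HeadingParams(alpha=0.0, w=0.5, kappa=6.0),
            theta0=0.0, **base)
    if kind == "wind_skewed":
        return Scenario(
            name="wind_skewed",
            heading_spec=HeadingModelSpec(Family.CAR, Noise.KJ),
            heading_params=HeadingParams(alpha=-np.pi / 8, w=0.7, kappa=6.0,
                                         r=0.3, lambda_=5 * np.pi / 8),
            theta0=-np.pi / 8, **base)
    if kind == "zigzag":
        return Scenario(
            name="zigzag",
            heading_spec=HeadingModelSpec(Family.CAR, Noise.VM),
            heading_params=HeadingParams(alpha=0.0, w=-0.5, kappa=6.0),
            theta0=0.3, **base)
    if kind == "tortuous_loop":
        return Scenario(
            name="tortuous_loop",
            heading_spec=HeadingModelSpec(Family.CAR, Noise.KJ),
            heading_params=HeadingParams(alpha=3 * np.pi / 4, w=0.85, kappa=4.0,
                                         r=0.5, lambda_=-np.pi / 2),
            theta0=3 * np.pi / 4, **base)
    if kind == "homing":
        return Scenario(
            name="homing",
            heading_spec=HeadingModelSpec(Family.CAR, Noise.KJ,
                                          constraint=FocalPoint(0.0, 30_000.0)),
            heading_params=HeadingParams(w=0.8, kappa=8.0, r=0.2,
                                         lambda_=5 * np.pi / 8),
            theta0=np.pi / 4, **base)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
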