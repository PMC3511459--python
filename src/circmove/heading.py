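"""Heading models: correlated random walk and circular auto-regression.

The circular auto-regression (C-AR) posits that the next heading is drawn
around a conditional mean obtained by attracting the previous heading toward
a focal direction ``alpha``:

    theta_t = M(theta_{t-1}; alpha, w) + e_t        (symmetric VM/WC noise)

or, to capture asymmetric external forcing (e.g. wind blowing toward a
leeward direction ``lambda``),

    theta_t ~ KJ(mu_t, kappa, r, nu_t),  mu_t = M(theta_{t-1}; alpha, w),
                                         nu_t = lambda - mu_t,

so each step's error distribution is skewed from the intended direction
``mu_t`` toward ``lambda``.  The correlated random walk is the ``w = 1``
special case.  Fitting is by conditional maximum likelihood (conditional on
the first observed heading) with multi-start quasi-Newton optimisation, and
models are compared by AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize

from .circular import (
    attraction_map,
    circular_mean,
    kj_logpdf,
    vm_logpdf,
    wc_logpdf,
    wrap,
)
from .trajectory import StepSeries

__all__ = [
    "Family",
    "Noise",
    "FixedLambda",
    "FixedAlpha",
    "FocalPoint",
    "HeadingModelSpec",
    "HeadingParams",
    "StartRecord",
    "FitResult",
    "step_mean",
    "heading_loglik",
    "fit_heading",
    "select_model",
    "heading_residuals",
]


class Family(str, Enum):
    CRW = "crw"
    CAR = "car"


class Noise(str, Enum):
    VM = "vm"
    WC = "wc"
    KJ = "kj"


@dataclass(frozen=True)
class FixedLambda:
    """Constrain the skew target to a known direction (e.g. the leeward
    direction estimated from the speed model at time unit 1)."""

    value: float


@dataclass(frozen=True)
class FixedAlpha:
    """Constrain the focal direction, e.g. to the entire observed flight
    direction (bearing from first to last fix)."""

    value: float


@dataclass(frozen=True)
class FocalPoint:
    """Replace the focal direction by the bearing from the current location
    to a fixed focal point (homing toward a nest site)."""

    x: float
    y: float


Constraint = Union[None, FixedLambda, FixedAlpha, FocalPoint]


@dataclass(frozen=True)
class HeadingModelSpec:
    """Model family, noise distribution and optional constraint."""

    family: Family = Family.CAR
    noise: Noise = Noise.VM
    constraint: Constraint = None

    def __post_init__(self):
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "noise", Noise(self.noise))
        if isinstance(self.constraint, FixedLambda) and self.noise is not Noise.KJ:
            raise ValueError("fixed-lambda constraint requires Kato-Jones noise")
        if isinstance(self.constraint, (FixedAlpha, FocalPoint)) and self.family is not Family.CAR:
            raise ValueError("alpha constraints require the C-AR family (CRW has no alpha)")

    @property
    def has_alpha(self) -> bool:
        return self.family is Family.CAR and not isinstance(self.constraint, FocalPoint)

    @property
    def free_names(self) -> Tuple[str, ...]:
        names: List[str] = []
        if self.family is Family.CAR:
            if self.has_alpha and not isinstance(self.constraint, FixedAlpha):
                names.append("alpha")
            names.append("w")
        if self.noise in (Noise.VM, Noise.KJ):
            names.append("kappa")
        if self.noise in (Noise.WC, Noise.KJ):
            names.append("r")
        if self.noise is Noise.KJ and not isinstance(self.constraint, FixedLambda):
            names.append("lambda_")
        return tuple(names)

    @property
    def n_free_params(self) -> int:
        return len(self.free_names)

    @property
    def needs_locations(self) -> bool:
        return isinstance(self.constraint, FocalPoint)

    def label(self) -> str:
        s = f"{self.family.value}({self.noise.value})"
        if isinstance(self.constraint, FixedLambda):
            s += f"[lambda={self.constraint.value:.3f}]"
        elif isinstance(self.constraint, FixedAlpha):
            s += f"[alpha={self.constraint.value:.3f}]"
        elif isinstance(self.constraint, FocalPoint):
            s += f"[fp=({self.constraint.x:.0f},{self.constraint.y:.0f})]"
        return s


@dataclass(frozen=True)
class HeadingParams:
    """Parameter vector; fields the spec fixes or omits are ``None``."""

    alpha: Optional[float] = None
    w: Optional[float] = None
    kappa: Optional[float] = None
    r: Optional[float] = None
    lambda_: Optional[float] = None

    def resolved(self, spec: HeadingModelSpec) -> "HeadingParams":
        """Fill fixed/implied fields from the spec (w=1 for CRW, constrained
        alpha/lambda), validating presence of every needed free field."""
        d = dict(alpha=self.alpha, w=self.w, kappa=self.kappa, r=self.r,
                 lambda_=self.lambda_)
        if spec.family is Family.CRW:
            d["w"] = 1.0
            d["alpha"] = None
        if isinstance(spec.constraint, FixedAlpha):
            d["alpha"] = wrap(spec.constraint.value)
        if isinstance(spec.constraint, FixedLambda):
            d["lambda_"] = wrap(spec.constraint.value)
        if spec.noise is Noise.VM:
            d["r"] = None
            d["lambda_"] = None
        if spec.noise is Noise.WC:
            d["kappa"] = None
            d["lambda_"] = None
        for name in spec.free_names:
            if d[name] is None:
                raise ValueError(f"missing parameter {name!r} for {spec.label()}")
        return HeadingParams(**d)


@dataclass(frozen=True)
class StartRecord:
    x0: Tuple[float, ...]
    loglik: float
    success: bool


@dataclass(frozen=True)
class FitResult:
    spec: HeadingModelSpec
    params: HeadingParams
    loglik: float
    aic: float
    n_steps: int
    starts: Tuple[StartRecord, ...] = field(default_factory=tuple)
    failed: bool = False
    message: str = ""

    @property
    def k(self) -> int:
        return self.spec.n_free_params


# ---------------------------------------------------------------------------
# conditional mean and likelihood
# ---------------------------------------------------------------------------

def _alpha_of(spec: HeadingModelSpec, params: HeadingParams, locations):
    """Per-step attraction target: the focal direction, or the bearing from
    each current location to the focal point."""
    if isinstance(spec.constraint, FocalPoint):
        if locations is None:
            raise ValueError("focal-point models require current locations")
        loc = np.atleast_2d(np.asarray(locations, dtype=float))
        return np.arctan2(spec.constraint.y - loc[:, 1], spec.constraint.x - loc[:, 0])
    return params.alpha


def step_mean(theta_prev, spec: HeadingModelSpec, params: HeadingParams,
              current_location=None):
    """Conditional mean heading mu_t given the previous heading.

    For CRW this is the previous heading itself; for C-AR it is the attraction
    map M(theta_prev; alpha, w); for focal-point models alpha is replaced by
    the bearing from ``current_location`` to the focal point.
    """
    params = params.resolved(spec)
    if spec.family is Family.CRW:
        out = wrap(theta_prev)
        return out
    if isinstance(spec.constraint, FocalPoint):
        if current_location is None:
            raise ValueError("focal-point models require the current location")
        alpha = _alpha_of(spec, params, current_location)
        alpha = float(alpha[0]) if np.ndim(theta_prev) == 0 else alpha
    else:
        alpha = params.alpha
    return attraction_map(theta_prev, alpha, params.w)


def _mu_nu_series(headings, spec, params, locations):
    """Vector of mu_t (and nu_t for KJ noise) for t = 1..n-1."""
    th_prev = headings[:-1]
    if spec.family is Family.CRW:
        mu = wrap(th_prev)
    elif isinstance(spec.constraint, FocalPoint):
        if locations is None:
            raise ValueError("focal-point models require the fix locations")
        loc = np.asarray(locations, dtype=float)
        if loc.shape[0] < headings.size:
            raise ValueError("need one location per step start")
        alpha_t = np.arctan2(spec.constraint.y - loc[1:headings.size, 1],
                             spec.constraint.x - loc[1:headings.size, 0])
        u = wrap(th_prev - alpha_t)
        mu = wrap(alpha_t + 2.0 * np.arctan(params.w * np.tan(0.5 * u)))
    else:
        mu = attraction_map(th_prev, params.alpha, params.w)
    if spec.noise is Noise.KJ:
        nu = wrap(params.lambda_ - mu)
        return mu, nu
    return mu, None


def heading_loglik(series: StepSeries, spec: HeadingModelSpec,
                   params: HeadingParams, locations=None) -> float:
    """Conditional log-likelihood of the heading series (no term for the
    first heading, which is conditioned on)."""
    headings = np.asarray(series.headings, dtype=float)
    if headings.size < 2:
        raise ValueError("need at least two headings")
    if np.any(~np.isfinite(headings)):
        raise ValueError("series contains undefined headings")
    params = params.resolved(spec)
    if locations is None:
        locations = getattr(series, "fixes", None)
    mu, nu = _mu_nu_series(headings, spec, params, locations)
    th = headings[1:]
    if spec.noise is Noise.VM:
        ll = vm_logpdf(wrap(th - mu), 0.0, params.kappa)
    elif spec.noise is Noise.WC:
        ll = wc_logpdf(wrap(th - mu), 0.0, params.r)
    else:
        ll = kj_logpdf(th, mu, params.kappa, params.r, nu)
    return float(np.sum(ll))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _logit(p):
    return math.log(p / (1.0 - p))


def _expit(z):
    return 1.0 / (1.0 + math.exp(-z))


def _pack(params: HeadingParams, spec: HeadingModelSpec) -> np.ndarray:
    z = []
    for name in spec.free_names:
        v = getattr(params, name)
        if name == "kappa":
            z.append(math.log(v))
        elif name == "r":
            z.append(_logit(min(max(v, 1e-6), 1 - 1e-9)))
        else:
            z.append(float(v))
    return np.asarray(z)


def _unpack(z: np.ndarray, spec: HeadingModelSpec) -> HeadingParams:
    d = {}
    for name, v in zip(spec.free_names, z):
        if name == "kappa":
            d[name] = math.exp(min(v, 25.0))
        elif name == "r":
            d[name] = _expit(v)
        elif name in ("alpha", "lambda_"):
            d[name] = wrap(v)
        else:
            d[name] = float(v)
    return HeadingParams(**d)


def _start_designs(spec: HeadingModelSpec, series: StepSeries,
                   rng: np.random.Generator, n_starts: int) -> List[HeadingParams]:
    """Stratified multi-start design: circular grid for angles, spread of
    regression/concentration values, plus one data-informed start at the
    circular mean heading."""
    headings = np.asarray(series.headings, dtype=float)
    mean_dir = circular_mean(headings)
    alpha_grid = wrap(mean_dir + np.array([0.0, np.pi / 2, np.pi, -np.pi / 2]))
    w_grid = [-0.5, 0.3, 0.7, 0.95]
    kappa_grid = [1.0, 10.0]
    r_grid = [0.1, 0.5]
    lam_grid = wrap(mean_dir + np.array([0.0, 2 * np.pi / 3, -2 * np.pi / 3]))

    starts: List[HeadingParams] = []
    smart = HeadingParams(alpha=mean_dir, w=0.7, kappa=4.0, r=0.2,
                          lambda_=wrap(mean_dir + 0.5))
    starts.append(smart)
    while len(starts) < n_starts:
        starts.append(HeadingParams(
            alpha=float(rng.choice(alpha_grid)),
            w=float(rng.choice(w_grid)),
            kappa=float(rng.choice(kappa_grid)),
            r=float(rng.choice(r_grid)),
            lambda_=float(rng.choice(lam_grid)),
        ))
    return starts[:n_starts]


def fit_heading(series: StepSeries, spec: HeadingModelSpec, n_starts: int = 8,
                seed: int = 0, locations=None,
                extra_starts: Sequence[HeadingParams] = ()) -> FitResult:
    """Maximum-likelihood fit by multi-start quasi-Newton (BFGS) optimisation.

    Free parameters are optimised on unconstrained scales (log kappa, logit r,
    angles periodic, w unbounded).  The best converged start is retained; a
    start counts as converged when the finite-difference gradient norm falls
    below 1e-4.  Deterministic given ``seed``.
    """
    headings = np.asarray(series.headings, dtype=float)
    if headings.size < 10:
        raise ValueError("series too short to fit (need >= 10 headings)")
    if np.any(~np.isfinite(headings)):
        raise ValueError("series contains undefined headings; drop those steps first")
    rng = np.random.default_rng(seed)
    if locations is None:
        locations = getattr(series, "fixes", None)
    n_terms = headings.size - 1

    def negll(z):
        try:
            p = _unpack(z, spec).resolved(spec)
            ll = heading_loglik(series, spec, p, locations)
        except (ValueError, OverflowError, FloatingPointError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    starts = list(extra_starts) + _start_designs(spec, series, rng, n_starts)
    records: List[StartRecord] = []
    best = None
    for s in starts:
        try:
            z0 = _pack(s.resolved(spec), spec)
        except ValueError:
            continue
        res = optimize.minimize(negll, z0, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        # finite-difference gradient noise scales with |f|; tolerance relative
        gtol = 1e-4 * max(1.0, abs(float(res.fun)))
        grad_ok = np.max(np.abs(res.jac)) < gtol if res.jac is not None else False
        ok = bool(res.success or grad_ok) and np.isfinite(res.fun) and res.fun < 1e11
        records.append(StartRecord(tuple(np.round(z0, 6)), -float(res.fun), ok))
        if ok and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        return FitResult(spec, HeadingParams(), -np.inf, np.inf, n_terms,
                         tuple(records), failed=True,
                         message="no optimisation start converged")
    params = _unpack(best.x, spec).resolved(spec)
    params = _canonicalize(params, spec)
    loglik = -float(best.fun)
    aic = -2.0 * loglik + 2.0 * spec.n_free_params
    return FitResult(spec, params, loglik, aic, n_terms, tuple(records))


def _canonicalize(params: HeadingParams, spec: HeadingModelSpec) -> HeadingParams:
    """Resolve the exact aliasing M(theta; alpha + pi, w) = M(theta; alpha, 1/w)
    of the attraction map by reporting the representative with |w| <= 1.
    Only applies when alpha is a free direction (for a fixed alpha or a focal
    point the alias is not reachable and w is identified as-is)."""
    if (params.w is not None and params.alpha is not None
            and spec.has_alpha and not isinstance(spec.constraint, FixedAlpha)
            and abs(params.w) > 1.0):
        return replace(params, alpha=wrap(params.alpha + np.pi), w=1.0 / params.w)
    return params


def _embed_params(fit: FitResult, target: HeadingModelSpec) -> Optional[HeadingParams]:
    """Best-effort embedding of a fitted nested model as a start for a richer
    one (CRW -> C-AR via w=1; symmetric noise -> KJ via small r)."""
    p = fit.params
    d = dict(alpha=p.alpha, w=p.w, kappa=p.kappa, r=p.r, lambda_=p.lambda_)
    if d["alpha"] is None:
        d["alpha"] = 0.0
    if d["w"] is None:
        d["w"] = 1.0
    if target.noise is Noise.KJ:
        if d["kappa"] is None:
            d["kappa"] = 2.0
        if d["r"] is None or d["r"] < 1e-4:
            d["r"] = 0.02
        if d["lambda_"] is None:
            d["lambda_"] = wrap(d["alpha"] + 0.3)
    if target.noise is Noise.VM and d["kappa"] is None:
        d["kappa"] = 2.0
    if target.noise is Noise.WC and d["r"] is None:
        d["r"] = 0.3
    try:
        return HeadingParams(**d).resolved(target)
    except ValueError:
        return None


def select_model(series: StepSeries, candidates: Sequence[HeadingModelSpec],
                 n_starts: int = 8, seed: int = 0, locations=None) -> List[FitResult]:
    """Fit every candidate and rank by AIC (ties: fewer parameters, then
    declaration order).  Nested fits are reused as warm starts for richer
    candidates, which keeps the maximised likelihoods monotone across nested
    families.  Per-candidate failures are returned as flagged entries."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    fits: List[FitResult] = []
    done: List[FitResult] = []
    for i, spec in enumerate(candidates):
        extra = []
        for f in done:
            if not f.failed:
                e = _embed_params(f, spec)
                if e is not None:
                    extra.append(e)
        try:
            fit = fit_heading(series, spec, n_starts=n_starts, seed=seed + i,
                              locations=locations, extra_starts=extra)
        except ValueError as exc:
            fit = FitResult(spec, HeadingParams(), -np.inf, np.inf, 0,
                            failed=True, message=str(exc))
        fits.append(fit)
        done.append(fit)
    order = sorted(range(len(fits)),
                   key=lambda i: (fits[i].aic, fits[i].k, i))
    return [fits[i] for i in order]


def heading_residuals(series: StepSeries, fit: FitResult, locations=None) -> np.ndarray:
    """Per-step innovations: wrapped differences from the conditional mean for
    symmetric noise; the inverse generating transform (which recovers the
    underlying VM(0, kappa) errors) for Kato-Jones noise."""
    headings = np.asarray(series.headings, dtype=float)
    params = fit.params.resolved(fit.spec)
    if locations is None:
        locations = getattr(series, "fixes", None)
    mu, nu = _mu_nu_series(headings, fit.spec, params, locations)
    th = headings[1:]
    if fit.spec.noise is not Noise.KJ:
        return wrap(th - mu)
    omega = (1.0 - params.r) / (1.0 + params.r)
    u = wrap(th - mu - nu)
    return wrap(nu + 2.0 * np.arctan(np.tan(0.5 * u) / omega))
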