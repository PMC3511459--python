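"""Circular arithmetic, the attraction map, and circular error distributions.

Angles are radians on ``[-pi, pi)`` with the compass convention 0 = east,
``pi/2`` = north, ``pi`` = west, ``-pi/2`` = south.  Three error families are
provided: the symmetric von Mises (VM) and wrapped Cauchy (WC) distributions,
and the four-parameter Kato-Jones (KJ) family, an asymmetric distribution
obtained by pushing a von Mises variate through a Moebius (tan-half-angle)
attraction toward ``nu`` followed by a rotation by ``mu``.  The same
tan-half-angle map, parameterised by a focal direction ``alpha`` and a
regression coefficient ``w``, is the attraction map of the circular
auto-regression implemented in :mod:`circmove.heading`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "TWO_PI",
    "wrap",
    "circular_mean",
    "attraction_map",
    "attraction_map_inverse",
    "VonMisesParams",
    "WrappedCauchyParams",
    "KatoJonesParams",
    "vm_pdf",
    "vm_logpdf",
    "wc_pdf",
    "wc_logpdf",
    "kj_pdf",
    "kj_logpdf",
    "kj_pdf_via_transform",
    "kj_generating_transform",
    "kj_inverse_transform",
    "sample_vm",
    "sample_wc",
    "sample_kj",
    "sample_circular",
    "KJSummaries",
    "kj_summaries",
]

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# angle arithmetic
# ---------------------------------------------------------------------------

def wrap(theta):
    """Wrap angle(s) to the half-open interval ``[-pi, pi)``.

    Parameters
    ----------
    theta : float or array_like
        Angle(s) in radians; must be finite.

    Returns
    -------
    float or ndarray
        ``theta`` reduced modulo ``2*pi`` into ``[-pi, pi)``.
    """
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("angles must be finite")
    out = np.mod(arr + np.pi, TWO_PI) - np.pi
    # mod can return exactly 2*pi - eps -> fine; but +pi itself maps to -pi
    if arr.ndim == 0:
        return float(out)
    return out


def circular_mean(theta) -> float:
    """Direction of the resultant vector of a sample of angles."""
    arr = np.asarray(theta, dtype=float)
    return float(np.arctan2(np.sin(arr).sum(), np.cos(arr).sum()))


def _tan_half(u):
    """tan(u/2) with u in [-pi, pi); the seam u = -pi stays finite in floats."""
    return np.tan(0.5 * u)


def attraction_map(theta, alpha, w):
    """Smooth circle map pulling ``theta`` toward the focal direction ``alpha``.

    ``M(theta; alpha, w) = alpha + 2*arctan(w * tan((theta - alpha)/2))``.

    ``w = 1`` is the identity (the correlated-random-walk limit), ``w = 0``
    collapses every angle onto ``alpha``, ``0 < w < 1`` attracts toward
    ``alpha``, and ``w < 0`` reflects across ``alpha``, producing reciprocating
    (zigzag) headings.  The antipode ``theta = alpha + pi`` is mapped to its
    continuous limit ``alpha + pi``.
    """
    u = wrap(np.asarray(theta, dtype=float) - alpha)
    w = float(w)
    if w == 0.0:
        out = np.full(np.shape(u), wrap(alpha))
        return wrap(alpha) if np.ndim(theta) == 0 else out
    at_seam = np.isclose(np.abs(u), np.pi)
    m = 2.0 * np.arctan(w * _tan_half(np.where(at_seam, 0.0, u)))
    m = np.where(at_seam, np.pi, m)
    out = wrap(alpha + m)
    return float(out) if np.ndim(theta) == 0 else out


def attraction_map_inverse(y, alpha, w):
    """Inverse of :func:`attraction_map`; requires ``w != 0``."""
    if w == 0.0:
        raise ValueError("attraction map is not invertible for w = 0")
    return attraction_map(y, alpha, 1.0 / w)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VonMisesParams:
    """von Mises distribution VM(mu, kappa); kappa > 0."""

    mu: float
    kappa: float

    def __post_init__(self):
        if not np.isfinite(self.mu) or not np.isfinite(self.kappa):
            raise ValueError("von Mises parameters must be finite")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        object.__setattr__(self, "mu", wrap(self.mu))


@dataclass(frozen=True)
class WrappedCauchyParams:
    """Wrapped Cauchy distribution WC(mu, r); 0 <= r < 1."""

    mu: float
    r: float

    def __post_init__(self):
        if not np.isfinite(self.mu) or not np.isfinite(self.r):
            raise ValueError("wrapped Cauchy parameters must be finite")
        if not 0.0 <= self.r < 1.0:
            raise ValueError(f"r must lie in [0, 1), got {self.r}")
        object.__setattr__(self, "mu", wrap(self.mu))


@dataclass(frozen=True)
class KatoJonesParams:
    """Kato-Jones distribution KJ(mu, kappa, r, nu).

    Generated from X ~ VM(0, kappa) by attracting X toward ``nu`` with Moebius
    coefficient ``(1 - r)/(1 + r)`` and rotating by ``mu``; the mass therefore
    shifts from ``mu`` toward ``mu + nu``, with a mode between the two and a
    tail toward ``mu``.
    """

    mu: float
    kappa: float
    r: float
    nu: float

    def __post_init__(self):
        vals = (self.mu, self.kappa, self.r, self.nu)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("Kato-Jones parameters must be finite")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if not 0.0 <= self.r < 1.0:
            raise ValueError(f"r must lie in [0, 1), got {self.r}")
        object.__setattr__(self, "mu", wrap(self.mu))
        object.__setattr__(self, "nu", wrap(self.nu))


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def vm_logpdf(y, mu, kappa):
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    y = np.asarray(y, dtype=float)
    # log I0(kappa) = log(i0e(kappa)) + kappa, stable for large kappa
    return kappa * (np.cos(y - mu) - 1.0) - np.log(TWO_PI * special.i0e(kappa))


def vm_pdf(y, p: VonMisesParams):
    """von Mises density exp(kappa*cos(y-mu)) / (2*pi*I0(kappa))."""
    out = np.exp(vm_logpdf(y, p.mu, p.kappa))
    return float(out) if np.ndim(y) == 0 else out


def wc_logpdf(y, mu, r):
    if not 0.0 <= r < 1.0:
        raise ValueError("r must lie in [0, 1)")
    y = np.asarray(y, dtype=float)
    return np.log1p(-r * r) - np.log(TWO_PI) - np.log1p(r * r - 2.0 * r * np.cos(y - mu))


def wc_pdf(y, p: WrappedCauchyParams):
    """Wrapped Cauchy density (1-r^2) / (2*pi*(1 + r^2 - 2*r*cos(y-mu)))."""
    out = np.exp(wc_logpdf(y, p.mu, p.r))
    return float(out) if np.ndim(y) == 0 else out


def kj_logpdf(y, mu, kappa, r, nu):
    """Log Kato-Jones density; ``mu``/``nu`` may be arrays (per-step params).

    Closed form: with gamma = mu + nu, D(y) = 1 + r^2 - 2 r cos(y - gamma),
    xi = |1 + r^2 e^{2 i nu}| and eta = mu + arg(1 + r^2 e^{2 i nu}),

        f(y) = (1 - r^2) / (2 pi I0(kappa))
               * exp(kappa * (xi * cos(y - eta) - 2 r cos nu) / D(y)) / D(y).
    """
    if np.any(np.asarray(kappa) <= 0):
        raise ValueError("kappa must be positive")
    if np.any((np.asarray(r) < 0) | (np.asarray(r) >= 1)):
        raise ValueError("r must lie in [0, 1)")
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    gamma = mu + nu
    z = 1.0 + r * r * np.exp(2j * nu)
    xi = np.abs(z)
    eta = mu + np.angle(z)
    d = 1.0 + r * r - 2.0 * r * np.cos(y - gamma)
    expo = kappa * (xi * np.cos(y - eta) - 2.0 * r * np.cos(nu)) / d
    # subtract kappa to pair with i0e's e^{-kappa} scaling
    return np.log1p(-r * r) + (expo - kappa) - np.log(TWO_PI * special.i0e(kappa)) - np.log(d)


def kj_pdf(y, p: KatoJonesParams):
    """Kato-Jones density (closed form)."""
    out = np.exp(kj_logpdf(y, p.mu, p.kappa, p.r, p.nu))
    return float(out) if np.ndim(y) == 0 else out


def kj_generating_transform(x, p: KatoJonesParams):
    """Map a VM(0, kappa) variate to a KJ(mu, kappa, r, nu) variate.

    ``y = mu + nu + 2*arctan(((1 - r)/(1 + r)) * tan((x - nu)/2))``: attraction
    toward ``nu`` with Moebius coefficient ``(1-r)/(1+r)``, then rotation by
    ``mu``.  With ``r = 0`` and ``nu = 0`` this is a pure rotation by ``mu``.
    """
    omega = (1.0 - p.r) / (1.0 + p.r)
    return wrap(p.mu + attraction_map(x, p.nu, omega))


def kj_inverse_transform(y, p: KatoJonesParams):
    """Inverse of :func:`kj_generating_transform` (recovers the VM variate)."""
    omega = (1.0 - p.r) / (1.0 + p.r)
    return attraction_map(wrap(np.asarray(y) - p.mu), p.nu, 1.0 / omega)


def kj_pdf_via_transform(y, p: KatoJonesParams):
    """Kato-Jones density by change of variables through the transform.

    ``f(y) = f_VM(g^{-1}(y); 0, kappa) * |d g^{-1}/ dy|`` with the Jacobian
    ``(1 - r^2) / (1 + r^2 - 2 r cos(y - mu - nu))``.  Kept as an independent
    route to cross-validate the closed form.
    """
    x = kj_inverse_transform(y, p)
    y = np.asarray(y, dtype=float)
    d = 1.0 + p.r * p.r - 2.0 * p.r * np.cos(y - p.mu - p.nu)
    jac = (1.0 - p.r * p.r) / d
    out = np.exp(vm_logpdf(x, 0.0, p.kappa)) * jac
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _rejection_sample(logpdf, log_fmax, n, rng, batch=4) -> np.ndarray:
    """Uniform-proposal rejection sampler on [-pi, pi).

    A uniform candidate x is accepted with probability f(x)/f_max (the
    acceptance ratio is normalised by the density maximum so that densities
    exceeding one are handled exactly).
    """
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(1024, batch * (n - filled))
        x = rng.uniform(-np.pi, np.pi, size=m)
        u = rng.uniform(size=m)
        acc = x[np.log(u) < logpdf(x) - log_fmax]
        take = min(n - filled, acc.size)
        out[filled : filled + take] = acc[:take]
        filled += take
    return out


def sample_vm(p: VonMisesParams, n: int, seed) -> np.ndarray:
    """Rejection-sample ``n`` von Mises variates (reproducible given seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    log_fmax = vm_logpdf(p.mu, p.mu, p.kappa)
    return _rejection_sample(lambda x: vm_logpdf(x, p.mu, p.kappa), log_fmax, n, rng)


def sample_wc(p: WrappedCauchyParams, n: int, seed) -> np.ndarray:
    """Rejection-sample ``n`` wrapped Cauchy variates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    log_fmax = wc_logpdf(p.mu, p.mu, p.r)
    return _rejection_sample(lambda x: wc_logpdf(x, p.mu, p.r), log_fmax, n, rng)


def sample_kj(p: KatoJonesParams, n: int, seed) -> np.ndarray:
    """Sample KJ variates by transforming von Mises draws (the generating
    construction itself)."""
    base = sample_vm(VonMisesParams(0.0, p.kappa), n, seed)
    return kj_generating_transform(base, p)


def sample_circular(p, n: int, seed) -> np.ndarray:
    """Dispatch on parameter type: VM, WC or KJ."""
    if isinstance(p, VonMisesParams):
        return sample_vm(p, n, seed)
    if isinstance(p, WrappedCauchyParams):
        return sample_wc(p, n, seed)
    if isinstance(p, KatoJonesParams):
        return sample_kj(p, n, seed)
    raise TypeError(f"unknown circular distribution parameters: {type(p)!r}")


# ---------------------------------------------------------------------------
# Kato-Jones summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KJSummaries:
    mode: float
    median: float
    quartiles: Tuple[float, float]
    multimodal: bool


def kj_summaries(p: KatoJonesParams, grid_size: int = 4096) -> KJSummaries:
    """Mode, median and quartiles of a Kato-Jones distribution.

    The mode is located numerically (dense grid plus bounded refinement, since
    no closed form is available); the median and quartiles are the images of
    the VM(0, kappa) quantiles under the generating transform.  If the density
    has several local maxima the global mode is returned and ``multimodal`` is
    flagged.
    """
    grid = np.linspace(-np.pi, np.pi, grid_size, endpoint=False)
    dens = kj_pdf(grid, p)
    # local maxima on the circular grid
    left = np.roll(dens, 1)
    right = np.roll(dens, -1)
    peaks = (dens > left) & (dens >= right)
    n_peaks = int(np.count_nonzero(peaks))
    i = int(np.argmax(dens))
    h = TWO_PI / grid_size
    res = optimize.minimize_scalar(
        lambda t: -kj_pdf(wrap(t), p),
        bounds=(grid[i] - h, grid[i] + h),
        method="bounded",
        options={"xatol": 1e-10},
    )
    mode = wrap(res.x)
    q25, q75 = stats.vonmises.ppf([0.25, 0.75], p.kappa, loc=0.0)
    median = float(kj_generating_transform(0.0, p))
    quartiles = (
        float(kj_generating_transform(q25, p)),
        float(kj_generating_transform(q75, p)),
    )
    return KJSummaries(mode=float(mode), median=median, quartiles=quartiles,
                       multimodal=n_peaks > 1)
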