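"""Residual screening, time-unit selection and goodness-of-fit tests.

Two global goodness-of-fit checks complement the stepwise likelihood:

* heading distribution — the observed headings are binned into 24 classes
  on ``[-pi, pi)`` and compared, via a chi-square statistic, with the mean
  class counts of many series simulated from the fitted model (classes with
  expected count < 3 excluded), together with pointwise 95% envelopes;
* final location — many full trajectories are simulated from the fitted
  heading + speed pair; the simulated endpoints are summarised by their mean
  and covariance, and the tail probability of the observed endpoint under
  the bivariate-normal approximation, ``P_FL = exp(-D^2/2)`` with ``D^2`` the
  Mahalanobis distance, rejects the model when below 0.05.

Residual whiteness (lag-1 autocorrelation inside the +-1.96/sqrt(n) band)
drives the choice of the time unit: the finest resampling interval at which
the innovations look independent is read as the pace at which the animal
controls its heading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .heading import (
    FitResult,
    HeadingModelSpec,
    fit_heading,
    heading_residuals,
    select_model,
)
from .simulate import Scenario, simulate_batch, simulate_heading_series
from .speed import SpeedFitResult
from .trajectory import StepSeries, Trajectory, derive_steps

__all__ = [
    "AutocorrResult",
    "GofReport",
    "FinalLocationReport",
    "TimeUnitRow",
    "TimeUnitReport",
    "lag1_autocorrelation",
    "heading_gof",
    "final_location_gof",
    "choose_time_unit",
    "BootstrapResult",
    "bootstrap_mle_distribution",
]

N_CLASSES = 24


@dataclass(frozen=True)
class AutocorrResult:
    rho1: float
    n: int
    significant: bool
    band: float


def lag1_autocorrelation(residuals) -> AutocorrResult:
    """Lag-1 autocorrelation of circular residuals treated as linear values
    (a small-angle white-noise approximation); significant when outside the
    +-1.96/sqrt(n) band."""
    x = np.asarray(residuals, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 residuals")
    x = x - x.mean()
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValueError("constant residuals: zero variance")
    rho1 = float(np.sum(x[1:] * x[:-1]) / denom)
    band = 1.96 / np.sqrt(x.size)
    return AutocorrResult(rho1=rho1, n=int(x.size), significant=abs(rho1) > band,
                          band=float(band))


@dataclass(frozen=True)
class GofReport:
    chi2: float
    pvalue: float
    df: int
    bin_edges: np.ndarray
    observed: np.ndarray            # O_d
    expected: np.ndarray            # E_d (mean simulated count per class)
    envelope_lo: np.ndarray         # 2.5 percentile of simulated counts
    envelope_hi: np.ndarray         # 97.5 percentile
    included: np.ndarray            # classes with E_d >= 3


def heading_gof(series: StepSeries, fit: FitResult, n_sim: int = 1000,
                seed: int = 0, speed_fit: Optional[SpeedFitResult] = None,
                locations=None) -> GofReport:
    """Chi-square test of the observed heading distribution against the
    fitted model's simulated heading distribution.

    ``n_sim`` heading series of the observed length are simulated from the
    fitted model, all starting at the observed first heading (focal-point
    models additionally need ``speed_fit`` to drive full trajectories).
    """
    if n_sim < 100:
        raise ValueError("need n_sim >= 100")
    n = series.n_steps
    theta0 = float(series.headings[0])
    if fit.spec.needs_locations:
        if speed_fit is None:
            raise ValueError("focal-point GOF needs a fitted speed model to "
                             "simulate trajectories")
        if locations is None:
            locations = series.fixes
        base = Scenario(name="gof", heading_spec=fit.spec,
                        heading_params=fit.params,
                        speed_params=speed_fit.params,
                        x0=float(locations[0, 0]), y0=float(locations[0, 1]),
                        theta0=theta0, v0=float(series.speeds[0]),
                        n_steps=n, time_unit=series.time_unit)
        sims = simulate_batch(base, n_sim, seed=seed)[0][:, 1:]
    else:
        sims = simulate_heading_series(fit.spec, fit.params, theta0, n - 1,
                                       n_sim, seed)[:, 1:]
    edges = np.linspace(-np.pi, np.pi, N_CLASSES + 1)
    obs_all = np.asarray(series.headings, dtype=float)[1:]
    observed = np.histogram(obs_all, edges)[0].astype(float)
    counts = np.apply_along_axis(lambda r: np.histogram(r, edges)[0], 1, sims).astype(float)
    expected = counts.mean(axis=0)
    lo, hi = np.percentile(counts, [2.5, 97.5], axis=0)
    included = expected >= 3.0
    if included.sum() < 3:
        raise ValueError("fewer than 3 classes with expected count >= 3: "
                         "test undefined")
    chi2 = float(np.sum((expected[included] - observed[included]) ** 2
                        / expected[included]))
    df = int(included.sum()) - 1
    pvalue = float(stats.chi2.sf(chi2, df))
    return GofReport(chi2=chi2, pvalue=pvalue, df=df, bin_edges=edges,
                     observed=observed, expected=expected, envelope_lo=lo,
                     envelope_hi=hi, included=included)


@dataclass(frozen=True)
class FinalLocationReport:
    mean: np.ndarray                # M, simulated endpoint mean (m)
    cov: np.ndarray                 # Sigma, simulated endpoint covariance
    observed: np.ndarray            # observed final fix
    mahalanobis_sq: float
    p_fl: float


def final_location_gof(series: StepSeries, heading_fit: FitResult,
                       speed_fit: SpeedFitResult, n_sim: int = 1000,
                       seed: int = 0) -> FinalLocationReport:
    """Tail probability of the observed final location under the
    bivariate-normal approximation to simulated endpoints.

    ``P_FL = exp(-D^2/2)`` is the normal mass outside the density contour
    through the observation (``D^2`` its Mahalanobis distance); the model is
    conventionally rejected when ``P_FL`` < 0.05, the contour at
    ``D^2 = 2 ln 20``.
    """
    if series.fixes is None:
        raise ValueError("series must carry its fixes")
    x0, y0 = series.fixes[0]
    base = Scenario(name="flgof", heading_spec=heading_fit.spec,
                    heading_params=heading_fit.params,
                    speed_params=speed_fit.params, x0=float(x0), y0=float(y0),
                    theta0=float(series.headings[0]),
                    v0=float(series.speeds[0]), n_steps=series.n_steps,
                    time_unit=series.time_unit)
    ends = simulate_batch(base, n_sim, seed=seed)[2]
    mean = ends.mean(axis=0)
    cov = np.cov(ends.T)
    obs = series.fixes[-1]
    try:
        sol = np.linalg.solve(cov, obs - mean)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate endpoint covariance") from exc
    d2 = float((obs - mean) @ sol)
    return FinalLocationReport(mean=mean, cov=cov, observed=np.asarray(obs),
                               mahalanobis_sq=d2, p_fl=float(np.exp(-d2 / 2.0)))


@dataclass(frozen=True)
class TimeUnitRow:
    time_unit: float
    fit: FitResult
    rho1: float
    rho1_significant: bool
    gof_pvalue: float
    acceptable: bool


@dataclass(frozen=True)
class TimeUnitReport:
    selected: Optional[float]
    rows: Tuple[TimeUnitRow, ...]


def choose_time_unit(traj: Trajectory, candidates: Sequence[float],
                     specs: Sequence[HeadingModelSpec], n_starts: int = 6,
                     seed: int = 0, n_sim: int = 500,
                     gof_level: float = 0.05) -> TimeUnitReport:
    """Smallest time unit whose AIC-best model has white residuals and an
    adequate heading goodness-of-fit.  Returns the full per-T table; if no
    candidate qualifies, ``selected`` is None (report-only outcome)."""
    rows: List[TimeUnitRow] = []
    selected = None
    for i, T in enumerate(candidates):
        try:
            series = derive_steps(traj, T)
            fits = select_model(series, specs, n_starts=n_starts, seed=seed + i)
            best = next(f for f in fits if not f.failed)
            res = heading_residuals(series, best)
            ac = lag1_autocorrelation(res)
            gof = heading_gof(series, best, n_sim=max(n_sim, 100), seed=seed + i)
        except (ValueError, StopIteration):
            continue
        ok = (not ac.significant) and gof.pvalue >= gof_level
        rows.append(TimeUnitRow(float(T), best, ac.rho1, ac.significant,
                                gof.pvalue, ok))
        if ok and selected is None:
            selected = float(T)
    return TimeUnitReport(selected=selected, rows=tuple(rows))


@dataclass(frozen=True)
class BootstrapResult:
    estimates: dict                 # name -> ndarray of replicate MLEs
    sd: dict                        # name -> standard deviation
    skewness: dict                  # name -> sample skewness
    n_requested: int
    n_failed: int


def bootstrap_mle_distribution(series: StepSeries, fit: FitResult,
                               n_boot: int = 200, seed: int = 0,
                               n_random_starts: int = 3) -> BootstrapResult:
    """Parametric bootstrap of the MLE distribution.

    Simulates ``n_boot`` heading series of the original length from the
    fitted model, refits each (using the fitted values as one start plus a
    few random starts), and summarises the per-parameter estimate
    distributions.  A strong right skew of kappa-hat at large kappa is
    expected: enlarging an already large concentration barely changes the
    von Mises shape.  Failed refits are excluded and counted.
    """
    if fit.spec.needs_locations:
        raise ValueError("bootstrap for focal-point models is not supported "
                         "without a speed model; fit the heading-only spec")
    n = series.n_steps
    theta0 = float(series.headings[0])
    sims = simulate_heading_series(fit.spec, fit.params, theta0, n - 1,
                                   n_boot, seed)
    names = fit.spec.free_names
    est = {name: [] for name in names}
    n_failed = 0
    for k in range(n_boot):
        boot = StepSeries(time_unit=series.time_unit, headings=sims[k],
                          speeds=np.ones(n))
        try:
            refit = fit_heading(boot, fit.spec, n_starts=n_random_starts,
                                seed=seed + 1000 + k,
                                extra_starts=[fit.params])
        except ValueError:
            refit = None
        if refit is None or refit.failed:
            n_failed += 1
            continue
        for name in names:
            est[name].append(getattr(refit.params, name))
    estimates = {k: np.asarray(v) for k, v in est.items()}
    sd = {}
    skew = {}
    for name, vals in estimates.items():
        if name in ("alpha", "lambda_"):
            # circular spread about the circular mean
            from .circular import circular_mean, wrap
            dev = wrap(vals - circular_mean(vals))
            sd[name] = float(np.sqrt(np.mean(dev ** 2)))
            skew[name] = float(stats.skew(dev))
        else:
            sd[name] = float(np.std(vals, ddof=1))
            skew[name] = float(stats.skew(vals))
    return BootstrapResult(estimates=estimates, sd=sd, skewness=skew,
                           n_requested=n_boot, n_failed=n_failed)
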