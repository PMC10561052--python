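"""Maximum-likelihood parameter inference and profile-likelihood
identifiability.

The objective is weighted least squares, i.e. twice the negative Gaussian
log-likelihood up to a constant: for datasets with per-point errors the
contribution is ``sum(((y - s*f)/sigma)**2)``; for datasets without errors a
per-dataset noise level is profiled analytically, giving ``n*log(SSR/n)``.
Dataset-specific scale factors (the arbitrary units of blots, co-IPs and
fluorescence traces) are profiled analytically by weighted least squares at
every objective evaluation, so the optimiser only sees the kinetic
parameters, which are handled on a log10 scale inside their fitting box.

Multi-start local optimisation (Latin-hypercube starts, bounded
trust-region least squares) guards against local minima; identifiability is
assessed by the profile likelihood: one parameter is stepped across its
range while all remaining free parameters are re-optimised, and the
confidence interval is the region where the profile stays within a
chi-square threshold (3.84 = pointwise 95%, one degree of freedom, by
default) of the global optimum.  Profiles that run into a bound of the
fitting box before crossing the threshold are classified as open on that
side (only the other confidence limit can be determined).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .datasets import ExperimentalDataset
from .observables import DEFAULT_OBSERVABLES, Observable
from .parameters import LOG10_BOUNDS, ParameterSet
from .simulate import IntegrationError, simulate

__all__ = [
    "FitResult",
    "LikelihoodProfile",
    "predict_observables",
    "objective",
    "fit",
    "profile_likelihood",
    "profile_cost_at",
]

#: Cost assigned when the ODE solver fails at a parameter point, so that
#: optimisers retreat instead of crashing.
FAILURE_COST = 1e8
_FAILURE_RESIDUAL = 1e4

DEFAULT_PROFILE_THRESHOLD = 3.84  # chi2(1) 95% quantile


def _protocol_key(ds: ExperimentalDataset) -> tuple:
    p = ds.protocol
    return (round(p.dose, 9), round(p.duration, 9), round(p.k_dnab, 12), ds.ab)


def _simulate_for(params: ParameterSet, datasets: list[ExperimentalDataset],
                  rtol: float, atol: float) -> dict:
    """One trajectory per unique (protocol, AB) pair, on the union of the
    data time points."""
    groups: dict[tuple, list[ExperimentalDataset]] = {}
    for ds in datasets:
        groups.setdefault(_protocol_key(ds), []).append(ds)
    cache = {}
    for key, members in groups.items():
        times = np.unique(np.concatenate([ds.times for ds in members]))
        horizon = float(times[-1]) if times[-1] > 0 else 1.0
        proto = members[0].protocol
        horizon = max(horizon, proto.duration * 1.0001)
        grid = np.unique(np.concatenate([[0.0, proto.duration, horizon], times]))
        grid = grid[grid <= horizon]
        p = params if members[0].ab == 1.0 else params.replace(AB=0.0)
        cache[key] = simulate(p, proto, horizon, grid=grid, rtol=rtol, atol=atol)
    return cache


def predict_observables(
    traj,
    ds: ExperimentalDataset,
    obs: Observable,
    scale: float = 1.0,
    offset: float = 0.0,
) -> np.ndarray:
    """Model prediction for a dataset's time points (affine observable map)."""
    return obs.predict(traj, ds.times, scale=scale, offset=offset)


def _profiled_scale(f: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted-LSQ-optimal scale for y ~ s*f (positive; 1 if degenerate)."""
    denom = float(np.sum(w * f * f))
    if denom <= 0:
        return 1.0
    s = float(np.sum(w * f * y)) / denom
    return s if s > 0 else 1.0


def objective(
    params: ParameterSet,
    datasets: list[ExperimentalDataset],
    observables: dict[str, Observable] | None = None,
    scales: dict[str, float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-6,
    return_residuals: bool = False,
):
    """Weighted least-squares cost of a parameter set on a dataset collection.

    Scale factors are taken from ``scales`` when given (keyed by dataset id)
    and otherwise profiled analytically per dataset.  A simulation failure
    yields the large sentinel cost :data:`FAILURE_COST`.
    """
    observables = observables or DEFAULT_OBSERVABLES
    try:
        cache = _simulate_for(params, datasets, rtol, atol)
    except IntegrationError:
        if return_residuals:
            n = sum(ds.n_points for ds in datasets)
            return np.full(n, _FAILURE_RESIDUAL)
        return FAILURE_COST

    cost = 0.0
    residuals = []
    for ds in datasets:
        traj = cache[_protocol_key(ds)]
        obs = observables[ds.observable_id]
        f = obs.predict(traj, ds.times)
        y = ds.values
        if ds.sigmas is not None:
            w = 1.0 / ds.sigmas**2
        else:
            w = np.ones_like(y)
        s = (scales or {}).get(ds.dataset_id)
        if s is None:
            s = _profiled_scale(f, y, w)
        r = np.sqrt(w) * (y - s * f)
        if ds.sigmas is not None:
            cost += float(np.sum(r * r))
            residuals.append(r)
        else:
            # noise level profiled analytically: -2 log L ~ n log(SSR/n)
            ssr = float(np.sum(r * r))
            n = ds.n_points
            cost += n * math.log(max(ssr, 1e-300) / n)
            residuals.append(r / max(math.sqrt(ssr / n), 1e-150))
    if return_residuals:
        return np.concatenate(residuals)
    return cost


@dataclass
class FitResult:
    """Outcome of a multi-start bounded maximum-likelihood fit."""

    params: ParameterSet              # best-fit parameter set
    free: tuple[str, ...]             # names of the fitted parameters
    log10_values: dict[str, float]    # best fit in log10 space
    cost: float                       # objective at the optimum
    starts: list[dict] = field(repr=False, default_factory=list)
    seed: int | None = None
    bounds: dict[str, tuple[float, float]] = field(repr=False, default_factory=dict)


def _apply_log10(base: ParameterSet, free: tuple[str, ...], x: np.ndarray) -> ParameterSet:
    return base.replace(**{name: 10.0 ** v for name, v in zip(free, x)})


def fit(
    datasets: list[ExperimentalDataset],
    base: ParameterSet,
    free: tuple[str, ...],
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    seed: int = 0,
    observables: dict[str, Observable] | None = None,
    include_base_start: bool = True,
    max_nfev: int = 120,
    rtol: float = 1e-6,
) -> FitResult:
    """Multi-start bounded least-squares estimation in log10 space.

    Starts are a seeded Latin hypercube over the fitting box (plus the
    ``base`` values as one deterministic start unless disabled); each start
    is refined with a bounded trust-region-reflective local optimisation
    and the best final cost wins.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    bounds = {**{name: LOG10_BOUNDS[name] for name in free}, **(bounds or {})}
    lo = np.array([bounds[name][0] for name in free])
    hi = np.array([bounds[name][1] for name in free])

    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    if include_base_start:
        x_base = np.clip(np.log10([getattr(base, n) for n in free]), lo, hi)
        starts = np.vstack([x_base, starts])

    def residual_fn(x):
        return objective(_apply_log10(base, free, x), datasets,
                         observables=observables, rtol=rtol, return_residuals=True)

    records = []
    best = None
    for x0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = least_squares(
                    residual_fn, x0, bounds=(lo, hi), method="trf",
                    diff_step=1e-4, max_nfev=max_nfev,
                )
            final = float(np.sum(sol.fun**2))
            rec = {"x0": x0.copy(), "x": sol.x.copy(), "cost": final,
                   "status": int(sol.status)}
        except Exception as exc:  # noqa: BLE001 - per-start diagnostics
            rec = {"x0": x0.copy(), "x": None, "cost": FAILURE_COST,
                   "status": -1, "error": repr(exc)}
        records.append(rec)
        if rec["x"] is not None and (best is None or rec["cost"] < best["cost"]):
            best = rec
    if best is None:
        raise RuntimeError(f"all {len(records)} starts failed: {records}")
    params = _apply_log10(base, free, best["x"])
    return FitResult(
        params=params,
        free=tuple(free),
        log10_values={n: float(v) for n, v in zip(free, best["x"])},
        cost=best["cost"],
        starts=records,
        seed=seed,
        bounds=bounds,
    )


def profile_cost_at(
    fit_result: FitResult,
    datasets: list[ExperimentalDataset],
    parameter: str,
    log10_value: float,
    observables: dict[str, Observable] | None = None,
    max_nfev: int = 60,
    rtol: float = 1e-6,
) -> float:
    """Re-optimised cost with one parameter fixed (a single profile point).

    The remaining free parameters are warm-started from the best fit.
    """
    others = tuple(n for n in fit_result.free if n != parameter)
    base = fit_result.params.replace(**{parameter: 10.0 ** log10_value})
    if not others:
        return float(objective(base, datasets, observables=observables, rtol=rtol))
    lo = np.array([fit_result.bounds[n][0] for n in others])
    hi = np.array([fit_result.bounds[n][1] for n in others])
    x0 = np.clip(np.array([fit_result.log10_values[n] for n in others]), lo, hi)

    def residual_fn(x):
        return objective(_apply_log10(base, others, x), datasets,
                         observables=observables, rtol=rtol, return_residuals=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(residual_fn, x0, bounds=(lo, hi), method="trf",
                            diff_step=1e-4, max_nfev=max_nfev)
    return float(np.sum(sol.fun**2))


@dataclass
class LikelihoodProfile:
    """A profile likelihood for one parameter."""

    parameter: str
    grid: np.ndarray                 # log10 values at which it was profiled
    costs: np.ndarray                # re-optimised cost per grid value
    best_log10: float
    best_cost: float
    threshold: float
    lower: float | None              # log10 CI bound, None if open (bound hit)
    upper: float | None

    @property
    def classification(self) -> str:
        if self.lower is not None and self.upper is not None:
            return "two-sided"
        if self.lower is not None:
            return "lower-only"
        if self.upper is not None:
            return "upper-only"
        return "unidentifiable"


def profile_likelihood(
    fit_result: FitResult,
    datasets: list[ExperimentalDataset],
    parameter: str,
    n_steps: int = 8,
    step: float = 0.25,
    threshold: float = DEFAULT_PROFILE_THRESHOLD,
    observables: dict[str, Observable] | None = None,
    max_nfev: int = 60,
    rtol: float = 1e-6,
) -> LikelihoodProfile:
    """Stepwise profile likelihood with warm starts.

    Walks outward from the best-fit value in steps of ``step`` log10 units
    (at most ``n_steps`` per direction), re-optimising the remaining free
    parameters at each point, and stops a direction once the profile
    exceeds ``best + threshold`` or the fitting box is reached.  Confidence
    limits are linear interpolations of the threshold crossing; a limit is
    ``None`` when the box edge is reached first (open interval, the
    "parameter boundary is reached" pattern).
    """
    if parameter not in fit_result.free:
        raise KeyError(f"{parameter!r} is not a free parameter of this fit")
    lo, hi = fit_result.bounds[parameter]
    x_best = fit_result.log10_values[parameter]
    grid = [x_best]
    costs = [fit_result.cost]

    limits: dict[int, float | None] = {}
    for direction in (-1, +1):
        x_prev, c_prev = x_best, fit_result.cost
        limit: float | None = None
        hit_box = True
        for k in range(1, n_steps + 1):
            x = x_best + direction * k * step
            if x < lo or x > hi:
                x = lo if direction < 0 else hi
            c = profile_cost_at(fit_result, datasets, parameter, x,
                                observables=observables, max_nfev=max_nfev,
                                rtol=rtol)
            grid.append(x)
            costs.append(c)
            if c > fit_result.cost + threshold:
                frac = (fit_result.cost + threshold - c_prev) / max(c - c_prev, 1e-12)
                limit = x_prev + frac * (x - x_prev)
                hit_box = False
                break
            x_prev, c_prev = x, c
            if x in (lo, hi):
                break
        limits[direction] = None if hit_box else limit

    order = np.argsort(grid)
    return LikelihoodProfile(
        parameter=parameter,
        grid=np.asarray(grid)[order],
        costs=np.asarray(costs)[order],
        best_log10=x_best,
        best_cost=fit_result.cost,
        threshold=threshold,
        lower=limits[-1],
        upper=limits[+1],
    )
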