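"""Time-resolved impact fractions for product-form fluxes.

For a mass-action flux ``v(t) = k * x(t) * y(t) [* z(t)]`` the logarithmic
derivative decomposes additively over the components::

    (dv/dt)/v = (dx/dt)/x + (dy/dt)/y [+ (dz/dt)/z]

The impact fraction of a component is its normalised relative rate of
change,

    omega_c = ((dc/dt)/c) / sum_k |(dk/dt)/k|,

so the absolute impact fractions sum to one at every time point and the sign
of omega_c says whether the component currently pushes the flux up or down.
A dominance threshold on |omega| (0.5 by default) labels the single
component that controls the change of the flux at each instant.

The method applies to mass-action product kinetics only; Hill-type fluxes do
not decompose this way and are rejected by :class:`FluxSpec` validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kinetics
from .model import species_index
from .simulate import Trajectory, _flux_index

__all__ = [
    "FluxSpec",
    "ImpactFractionSeries",
    "SIGNALOSOME_FORMATION",
    "IKK_ACTIVATION",
    "omega_from_rates",
    "impact_fractions",
    "dominant_component",
    "flux_auc",
    "cumulative_production",
]


@dataclass(frozen=True)
class FluxSpec:
    """A product-form flux: one rate constant times two or three species."""

    rate_constant: str
    components: tuple[str, ...]
    flux_id: str

    def __post_init__(self) -> None:
        if len(self.components) not in (2, 3):
            raise ValueError("impact fractions are defined for 2- or 3-component fluxes")
        for name in self.components:
            species_index(name)  # raises for unknown species
        _flux_index(self.flux_id)


#: The signalosome-formation hub: v15 = SFM_k1 * parPARP1 * pATM * IKKγ.
SIGNALOSOME_FORMATION = FluxSpec("SFM_k1", ("parPARP1", "pATM", "IKKg"), "v15")
#: The IKK-activation hub: v19 = TM_k3 * spIKKγ * ATT.
IKK_ACTIVATION = FluxSpec("TM_k3", ("spIKKg", "ATT"), "v19")


@dataclass
class ImpactFractionSeries:
    """Per-time impact fractions omega for each component of one flux."""

    times: np.ndarray          # (n,) seconds
    components: tuple[str, ...]
    omega: np.ndarray          # (n, n_components); NaN where invalid
    flux: np.ndarray           # (n,) flux values, molecules/s
    valid: np.ndarray          # (n,) bool mask where omega is defined
    flux_id: str

    @property
    def empty(self) -> bool:
        return not bool(self.valid.any())

    def to_frame(self) -> pd.DataFrame:
        """Long table (time_s, component, omega, flux, valid)."""
        frames = []
        for j, name in enumerate(self.components):
            frames.append(pd.DataFrame({
                "time_s": self.times,
                "component": name,
                "omega": self.omega[:, j],
                "flux": self.flux,
                "valid": self.valid,
            }))
        return pd.concat(frames, ignore_index=True)


def omega_from_rates(
    comps: np.ndarray,
    derivs: np.ndarray,
    eps: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Impact fractions from component values and their time derivatives.

    ``comps`` and ``derivs`` are ``(n_times, n_components)`` arrays; returns
    ``(omega, valid)`` where ``omega`` is NaN outside the validity mask
    (any component below ``eps``, or all relative derivatives zero).
    This is the core normalisation; :func:`impact_fractions` feeds it the
    analytic derivatives of a trajectory.
    """
    comps = np.asarray(comps, dtype=float)
    derivs = np.asarray(derivs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = derivs / comps
        denom = np.sum(np.abs(rel), axis=1)
        omega = rel / denom[:, None]
    valid = np.all(comps > eps, axis=1) & (denom > 0) & np.isfinite(denom)
    omega[~valid] = np.nan
    return omega, valid


def impact_fractions(
    traj: Trajectory,
    spec: FluxSpec,
    eps: float = 1e-6,
) -> ImpactFractionSeries:
    """Impact fraction of each component of a product-form flux over time.

    Component time derivatives are taken analytically from the ODE
    right-hand side at the stored states (no finite differencing).  Times
    where any component is below ``eps`` molecules, or where every relative
    derivative vanishes, are masked invalid rather than extrapolated.
    """
    k_value = getattr(traj.params, spec.rate_constant)
    idx = [species_index(name) for name in spec.components]
    comps = traj.states[:, idx]                      # (n, m)
    flux = traj.flux(spec.flux_id)

    product = k_value * np.prod(comps, axis=1)
    scale = np.maximum(np.abs(flux), np.abs(product))
    mismatch = np.abs(flux - product) > 1e-6 * np.maximum(scale, 1e-300)
    if mismatch.any():
        raise ValueError(
            f"flux {spec.flux_id} is not the product of {spec.rate_constant} "
            f"and {spec.components} on this trajectory; impact fractions "
            "require mass-action product kinetics"
        )

    p = traj.params.as_array()
    n = traj.times.size
    derivs = np.empty((n, len(idx)))
    for i in range(n):
        drive = traj.protocol.k_dnab * traj.protocol.dnab(traj.times[i])
        dy = _kinetics.rhs(traj.states[i], traj.times[i], p, drive)
        derivs[i] = dy[idx]

    omega, valid = omega_from_rates(comps, derivs, eps=eps)
    return ImpactFractionSeries(
        times=traj.times, components=spec.components, omega=omega,
        flux=flux, valid=valid, flux_id=spec.flux_id,
    )


def dominant_component(
    series: ImpactFractionSeries,
    threshold: float = 0.5,
) -> list[str | None]:
    """Per-time label of the component with ``|omega| > threshold``.

    Returns ``None`` where no component exceeds the threshold or where the
    fractions are undefined.  For thresholds >= 0.5 at most one component
    can qualify because the absolute fractions sum to one.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    labels: list[str | None] = []
    for i in range(series.times.size):
        if not series.valid[i]:
            labels.append(None)
            continue
        above = np.abs(series.omega[i]) > threshold
        if above.sum() == 1:
            labels.append(series.components[int(np.argmax(above))])
        else:
            labels.append(None)
    return labels


def _window_slice(traj: Trajectory, window) -> tuple[np.ndarray, np.ndarray]:
    t0, t1 = (traj.times[0], traj.times[-1]) if window is None else window
    if t0 < traj.times[0] or t1 > traj.times[-1] or t1 < t0:
        raise ValueError(
            f"window [{t0}, {t1}] outside trajectory span "
            f"[{traj.times[0]}, {traj.times[-1]}]"
        )
    return t0, t1


def _trapz_window(times: np.ndarray, values: np.ndarray, t0: float, t1: float) -> float:
    inner = (times >= t0) & (times <= t1)
    ts = times[inner]
    vs = values[inner]
    if ts.size == 0 or ts[0] > t0:
        ts = np.insert(ts, 0, t0)
        vs = np.insert(vs, 0, np.interp(t0, times, values))
    if ts[-1] < t1:
        ts = np.append(ts, t1)
        vs = np.append(vs, np.interp(t1, times, values))
    return float(np.trapezoid(vs, ts))


def flux_auc(traj: Trajectory, flux_id: str | int, window=None) -> float:
    """Area under a flux trace (molecules) by trapezoidal quadrature.

    For the signalosome-formation flux v15 integrated over the whole
    transient this equals the total number of IKKγ molecules ever modified,
    i.e. ``sig + spIKKγ + pIKK`` at the window end.
    """
    t0, t1 = _window_slice(traj, window)
    return _trapz_window(traj.times, traj.flux(flux_id), t0, t1)


def cumulative_production(traj: Trajectory, species: str, window=None) -> float:
    """Total molecules of a species ever produced in the window.

    Integrates the species' unique production flux, so recycling counts:
    the cumulative production of PARylated PARP-1 (production flux v8) can
    far exceed its instantaneous level because dePARylated molecules re-enter
    the cycle.  Species with several production fluxes are rejected with the
    candidate list.
    """
    from .model import STOICHIOMETRY

    row = STOICHIOMETRY[species_index(species)]
    producers = [f"v{i + 1}" for i in np.nonzero(row > 0)[0]]
    if len(producers) != 1:
        raise ValueError(
            f"species {species!r} has no unique production flux; "
            f"candidates: {producers or 'none'}"
        )
    t0, t1 = _window_slice(traj, window)
    return _trapz_window(traj.times, traj.flux(producers[0]), t0, t1)
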