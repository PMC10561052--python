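"""Finite-perturbation sensitivity analysis and in-silico inhibition scans.

The sensitivity coefficient of a parameter ``p`` at dose ``i`` is

    sc(p, i) = (pIKK*_perturbed - pIKK*) / pIKK*,

the relative change of the stimulated steady-state activated IKK complex
under a finite (by default 90%) reduction of ``p``.  A coefficient of -1
means complete suppression; positive coefficients are unbounded.  Inhibition
of a biological process maps to parameter reductions: ATM activation is the
pair ``k3 & k5``, PARP-1 auto-modification is ``vact``; an inhibition
efficiency ``e`` multiplies the target parameter(s) by ``1 - e``.

Perturbing a conserved total rescales the corresponding initial free-species
abundance with it (the initial state is built from the totals), which is the
only self-consistent reading of perturbing a moiety total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterSet, RATE_NAMES, TOTAL_NAMES
from .simulate import stimulated_steady_state
from .stimulus import StimulusProtocol

__all__ = [
    "PerturbationSpec",
    "PROCESS_TARGETS",
    "sensitivity_coefficient",
    "sensitivity_scan",
    "inhibition_grid",
]

#: Named inhibitable processes -> the parameters an inhibitor reduces.
PROCESS_TARGETS: dict[str, tuple[str, ...]] = {
    "atm": ("k3", "k5"),      # ATM activation (basal + feedback)
    "parp": ("vact",),        # PARP-1 auto-modification
}


@dataclass(frozen=True)
class PerturbationSpec:
    """A fractional change applied to one parameter or a parameter group.

    ``fraction`` is the relative change: -0.9 reduces the target(s) by 90%
    (an inhibition efficiency ``e`` corresponds to ``fraction = -e``).
    A fraction of exactly -1 is allowed only for the ``AB`` switch, whose
    value 0 is meaningful (catalytically dead PARP-1).
    """

    targets: tuple[str, ...]
    fraction: float

    def __post_init__(self) -> None:
        if isinstance(self.targets, str):
            object.__setattr__(self, "targets", (self.targets,))
        for t in self.targets:
            if t not in RATE_NAMES + TOTAL_NAMES + ("AB",):
                raise KeyError(f"unknown parameter {t!r}")
        factor = 1.0 + self.fraction
        if factor < 0:
            raise ValueError("fraction below -1 would make parameters negative")
        if factor == 0.0 and self.targets != ("AB",):
            raise ValueError("fraction -1 (zero value) is only allowed for AB")

    def apply(self, params: ParameterSet) -> ParameterSet:
        factor = 1.0 + self.fraction
        return params.replace(**{t: getattr(params, t) * factor for t in self.targets})


def sensitivity_coefficient(
    params: ParameterSet,
    pert: PerturbationSpec,
    dose: float,
    duration: float = 60.0,
    tol: float = 1e-9,
    horizon: float = 1e6,
    baseline_pikk: float | None = None,
) -> float:
    """Relative change of steady-state pIKK under a finite perturbation.

    ``baseline_pikk`` can be supplied to reuse an already computed
    unperturbed steady state (scan machinery); otherwise it is simulated.
    Returns NaN if the unperturbed steady state has no activated IKK.
    """
    protocol = StimulusProtocol.from_dose(dose, duration)
    if baseline_pikk is None:
        baseline_pikk = stimulated_steady_state(
            params, protocol, tol=tol, horizon=horizon
        ).pikk
    if baseline_pikk <= 0.0:
        return math.nan
    perturbed = stimulated_steady_state(
        pert.apply(params), protocol, tol=tol, horizon=horizon
    ).pikk
    return (perturbed - baseline_pikk) / baseline_pikk


def default_scan_parameters() -> list[str]:
    """All kinetic constants, all totals, and the combined ATM pair k3&k5."""
    singles = [n for n in RATE_NAMES if n not in ("km", "km2")]
    return singles + ["km", "km2"] + list(TOTAL_NAMES) + ["k3&k5"]


def _targets_for(label: str) -> tuple[str, ...]:
    return tuple(label.split("&"))


def sensitivity_scan(
    params: ParameterSet,
    parameters: Sequence[str] | None = None,
    doses: Iterable[float] = range(1, 101),
    reduction: float = 0.9,
    duration: float = 60.0,
    tol: float = 1e-9,
    horizon: float = 1e6,
) -> pd.DataFrame:
    """Sensitivity coefficients on a parameter x dose grid.

    ``reduction`` is the fractional decrease applied to each parameter (0.9
    = 90%); combined labels such as ``"k3&k5"`` reduce all listed parameters
    simultaneously.  Returns a frame indexed by parameter label with one
    column per dose (Gy).
    """
    labels = list(default_scan_parameters() if parameters is None else parameters)
    doses = [float(d) for d in doses]
    baseline = {
        d: stimulated_steady_state(
            params, StimulusProtocol.from_dose(d, duration), tol=tol, horizon=horizon
        ).pikk
        for d in doses
    }
    grid = np.empty((len(labels), len(doses)))
    for i, label in enumerate(labels):
        pert = PerturbationSpec(_targets_for(label), -reduction)
        for j, d in enumerate(doses):
            grid[i, j] = sensitivity_coefficient(
                params, pert, d, duration=duration, tol=tol, horizon=horizon,
                baseline_pikk=baseline[d],
            )
    return pd.DataFrame(grid, index=labels, columns=doses)


def inhibition_grid(
    params: ParameterSet,
    process: str,
    efficiencies: Iterable[float] = np.arange(0.0, 1.0, 0.01),
    doses: Iterable[float] = range(1, 101),
    duration: float = 60.0,
    tol: float = 1e-9,
    horizon: float = 1e6,
) -> pd.DataFrame:
    """Steady-state pIKK for each (inhibition efficiency, dose) cell.

    ``process`` is ``"atm"`` (simultaneous reduction of k3 and k5) or
    ``"parp"`` (reduction of vact); efficiency ``e`` multiplies the targets
    by ``1 - e``.  The efficiency-0 row reproduces the unperturbed
    dose-response curve.
    """
    try:
        targets = PROCESS_TARGETS[process]
    except KeyError:
        raise KeyError(
            f"unknown process {process!r}; known: {sorted(PROCESS_TARGETS)}"
        ) from None
    efficiencies = [float(e) for e in efficiencies]
    doses = [float(d) for d in doses]
    if any(not (0.0 <= e < 1.0) for e in efficiencies):
        raise ValueError("inhibition efficiencies must lie in [0, 1)")
    grid = np.empty((len(efficiencies), len(doses)))
    for i, e in enumerate(efficiencies):
        perturbed = params.scaled(targets, 1.0 - e) if e > 0 else params
        for j, d in enumerate(doses):
            grid[i, j] = stimulated_steady_state(
                perturbed, StimulusProtocol.from_dose(d, duration),
                tol=tol, horizon=horizon,
            ).pikk
    return pd.DataFrame(grid, index=efficiencies, columns=doses)
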