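"""Mapping model species onto assay observables.

Each experimental readout (recruitment fluorescence, immunoblot band,
co-immunoprecipitation, EMSA) reports an affine transform of a species or a
declared sum of species in arbitrary units: ``value = scale * expr + offset``.
Scales and offsets are dataset-specific nuisance quantities fitted (or
profiled) during inference; loading-control normalisation is assumed to have
been applied upstream by the quantification pipeline.

The default expression table reflects the conventional reading of each
assay: nuclear pATM blots report free phosphorylated ATM, cytoplasmic pATM
and TRAF6-complex blots report the cytoplasmic ATM-TRAF6(-TAK1) complexes,
recruitment fluorescence reports everything bound at the damage site, and
EMSA-detected NF-κB tracks the activated IKK complex.  All mappings can be
overridden per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import species_index
from .simulate import Trajectory

__all__ = ["Observable", "DEFAULT_OBSERVABLES"]

ASSAY_CLASSES = ("recruitment", "immunoblot", "coip", "emsa")


@dataclass(frozen=True)
class Observable:
    """A named, assay-classed sum of model species."""

    id: str
    expression: tuple[str, ...]
    assay: str

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_CLASSES:
            raise ValueError(f"unknown assay class {self.assay!r}; known: {ASSAY_CLASSES}")
        for name in self.expression:
            species_index(name)

    def evaluate(self, traj: Trajectory) -> np.ndarray:
        """The observable's model expression along a trajectory (molecules)."""
        idx = [species_index(s) for s in self.expression]
        return traj.states[:, idx].sum(axis=1)

    def predict(
        self,
        traj: Trajectory,
        times: np.ndarray,
        scale: float = 1.0,
        offset: float = 0.0,
    ) -> np.ndarray:
        """``scale * expression + offset`` interpolated onto ``times``."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        times = np.asarray(times, dtype=float)
        if times.min() < traj.times[0] or times.max() > traj.times[-1]:
            raise ValueError("requested times outside the trajectory span")
        raw = self.evaluate(traj)
        return scale * np.interp(times, traj.times, raw) + offset


DEFAULT_OBSERVABLES: dict[str, Observable] = {
    obs.id: obs
    for obs in (
        # GFP-PARP-1 fluorescence at the damage site: all DNA-bound PARP-1 forms
        Observable("parp_recruitment",
                   ("PARP1DSB_b", "PARP1_b", "parPARP1_b"), "recruitment"),
        # GFP-NBS1 / YFP-ATM at the damage site
        Observable("mrn_recruitment", ("MRN_b", "AMRN_b"), "recruitment"),
        Observable("atm_recruitment", ("AMRN_b",), "recruitment"),
        # phospho-ATM western blots, nuclear and cytoplasmic fractions
        Observable("patm_nuclear", ("pATM",), "immunoblot"),
        Observable("patm_cytoplasmic", ("AT", "ATT"), "immunoblot"),
        # co-IP of signalosome components
        Observable("signalosome", ("sig",), "coip"),
        # polyubiquitinated-TRAF6-containing complexes
        Observable("traf6_complex", ("AT", "ATT"), "immunoblot"),
        # EMSA of DNA-binding-active NF-κB, tracked by activated IKK
        Observable("nfkb_emsa", ("pIKK",), "emsa"),
    )
}
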