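"""The 20-species reaction network of DNA damage-induced IKK activation.

Nuclear events: irradiation exposes PARP-1 binding sites (``BS_P``) and MRN
binding sites (``BS_M``).  PARP-1 binds sites directly (``PARP1DSB_b``) or is
recruited by already PARylated, DNA-bound PARP-1 (``PARP1_b``); catalytically
active PARP-1 auto-modifies (``parPARP1_b``), dissociates (``parPARP1``) and
is dePARylated back to the free pool.  The MRN complex occupies ``BS_M``
(``MRN_b``, with a Hill-type positive feedback), recruits ATM (``AMRN_b``)
and activates it to ``pATM`` (second positive feedback).  PARylated PARP-1,
pATM and IKKγ form the signalosome (``sig``), which releases sumoylated,
phosphorylated IKKγ (``spIKKg``).  Cytoplasmic events: pATM polyubiquitinates
TRAF6 (``AT``), TAK1 joins to give the ``ATT`` complex, which catalyses the
irreversible conversion of spIKKγ into activated IKK complex (``pIKK``), the
model's readout.

All quantities are molecule numbers; time is in seconds.  The catalytic
switch ``AB`` gates the two PARylation fluxes (v6, v7): 1 for wild-type
PARP-1, 0 for the catalytically dead E988K variant.
"""

from __future__ import annotations

import numpy as np

from .parameters import PARAM_NAMES, ParameterSet
from .stimulus import StimulusProtocol

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "N_FLUXES",
    "STOICHIOMETRY",
    "MOIETIES",
    "reaction_rates",
    "ode_rhs",
    "initial_state",
    "moiety_residuals",
    "state_to_dict",
]

SPECIES: tuple[str, ...] = (
    "BS_P", "PARP1", "PARP1DSB_b", "PARP1_b", "parPARP1_b", "parPARP1",
    "BS_M", "MRN", "MRN_b", "AMRN_b", "ATM", "pATM",
    "IKKg", "sig", "spIKKg", "TRAF6", "AT", "ATT", "TAK1", "pIKK",
)
N_SPECIES = len(SPECIES)
N_FLUXES = 19

_IDX = {name: i for i, name in enumerate(SPECIES)}
_PIDX = {name: i for i, name in enumerate(PARAM_NAMES)}


def _build_stoichiometry() -> np.ndarray:
    """Signed flux coefficients of each species' time derivative."""
    terms = {
        "BS_P": {1: +1, 2: -1, 3: +1},
        "PARP1": {3: +1, 5: +1, 9: +1, 16: +1, 2: -1, 4: -1},
        "PARP1DSB_b": {2: +1, 3: -1, 6: -1},
        "PARP1_b": {4: +1, 5: -1, 7: -1},
        "parPARP1_b": {6: +1, 7: +1, 8: -1},
        "parPARP1": {8: +1, 9: -1, 15: -1},
        "BS_M": {1: +1, 10: -1, 11: -1},
        "MRN": {10: -1, 11: -1},
        "MRN_b": {10: +1, 11: +1, 12: -1, 13: +1, 14: +1},
        "AMRN_b": {12: +1, 13: -1, 14: -1},
        "ATM": {12: -1},
        "pATM": {13: +1, 14: +1, 15: -1, 16: +1, 17: -1},
        "IKKg": {15: -1},
        "sig": {15: +1, 16: -1},
        "spIKKg": {16: +1, 19: -1},
        "TRAF6": {17: -1},
        "AT": {17: +1, 18: -1},
        "ATT": {18: +1},
        "TAK1": {18: -1},
        "pIKK": {19: +1},
    }
    mat = np.zeros((N_SPECIES, N_FLUXES))
    for species, fluxes in terms.items():
        for flux_no, sign in fluxes.items():
            mat[_IDX[species], flux_no - 1] = sign
    return mat


STOICHIOMETRY: np.ndarray = _build_stoichiometry()
STOICHIOMETRY.setflags(write=False)

#: Conserved moieties: total name -> species whose sum is constant.
MOIETIES: dict[str, tuple[str, ...]] = {
    "PARP1_tot": ("PARP1", "PARP1DSB_b", "PARP1_b", "parPARP1_b", "parPARP1", "sig"),
    "MRN_tot": ("MRN", "MRN_b", "AMRN_b"),
    "ATM_tot": ("ATM", "AMRN_b", "pATM", "sig", "AT", "ATT"),
    "IKKg_tot": ("IKKg", "sig", "spIKKg", "pIKK"),
    "TRAF6_tot": ("TRAF6", "AT", "ATT"),
    "TAK1_tot": ("TAK1", "ATT"),
}


def _flux_vector(y: np.ndarray, p: np.ndarray, drive: float) -> np.ndarray:
    """The 19 reaction rates for state ``y`` (canonical species order).

    ``drive`` is the binding-site generation term ``k_DNAb * DNAb(t)``.
    """
    (bs_p, parp1, parp1dsb_b, parp1_b, parparp1_b, parparp1,
     bs_m, mrn, mrn_b, amrn_b, atm, patm,
     ikkg, sig, spikkg, traf6, at, att, tak1, _pikk) = y

    (kon, koff, kr, koff2, vact, koff_act, kdepar,
     k1, k4, k2, k3, k5,
     sfm_k1, sfm_k2, tm_k1, tm_k2, tm_k3,
     km, km2, n_hill,
     _parp1_tot, _mrn_tot, _atm_tot, _ikkg_tot, _traf6_tot, _tak1_tot,
     ab) = p

    mrn_b_n = mrn_b ** n_hill
    patm_n = patm ** n_hill

    v = np.empty(N_FLUXES)
    v[0] = drive                              # v1: binding-site generation
    v[1] = kon * parp1 * bs_p                 # v2: direct PARP-1 binding
    v[2] = koff * parp1dsb_b                  # v3: unbinding from the site
    v[3] = kr * parp1 * parparp1_b            # v4: recruitment by PARylated PARP-1
    v[4] = koff2 * parp1_b                    # v5: unbinding of recruited PARP-1
    v[5] = vact * parp1dsb_b * ab             # v6: PARylation at the site
    v[6] = vact * parp1_b * ab                # v7: PARylation of recruited PARP-1
    v[7] = koff_act * parparp1_b              # v8: release of PARylated PARP-1
    v[8] = kdepar * parparp1                  # v9: dePARylation
    v[9] = k1 * mrn * bs_m * mrn_b_n / (km + mrn_b_n)    # v10: MRN feedback recruitment
    v[10] = k4 * mrn * bs_m                   # v11: basal MRN recruitment
    v[11] = k2 * atm * mrn_b                  # v12: ATM recruitment to bound MRN
    v[12] = k3 * amrn_b * patm_n / (km2 + patm_n)        # v13: ATM activation feedback
    v[13] = k5 * amrn_b                       # v14: basal ATM activation
    v[14] = sfm_k1 * parparp1 * patm * ikkg   # v15: signalosome formation
    v[15] = sfm_k2 * sig                      # v16: signalosome disassembly
    v[16] = tm_k1 * patm * traf6              # v17: pATM-TRAF6 complex formation
    v[17] = tm_k2 * at * tak1                 # v18: TAK1 binding (ATT formation)
    v[18] = tm_k3 * spikkg * att              # v19: IKK complex activation
    return v


def reaction_rates(
    state: np.ndarray,
    params: ParameterSet,
    stimulus: StimulusProtocol,
    t: float,
) -> np.ndarray:
    """Evaluate the 19 reaction fluxes v1..v19 (molecules/s) at time ``t``."""
    y = np.asarray(state, dtype=float)
    if y.shape != (N_SPECIES,):
        raise ValueError(f"state must have {N_SPECIES} components, got {y.shape}")
    drive = stimulus.k_dnab * stimulus.dnab(t)
    return _flux_vector(y, params.as_array(), drive)


def ode_rhs(
    state: np.ndarray,
    params: ParameterSet,
    stimulus: StimulusProtocol,
    t: float,
) -> np.ndarray:
    """Time derivatives of all 20 species (molecules/s)."""
    return STOICHIOMETRY @ reaction_rates(state, params, stimulus, t)


def initial_state(params: ParameterSet) -> np.ndarray:
    """The canonical unstimulated rest state.

    All conserved mass sits in the free, unmodified species (PARP1, MRN,
    ATM, IKKγ, TRAF6, TAK1); every complex, binding site and modified form
    is zero.  With no irradiation this is an exact fixed point.
    """
    y0 = np.zeros(N_SPECIES)
    y0[_IDX["PARP1"]] = params.PARP1_tot
    y0[_IDX["MRN"]] = params.MRN_tot
    y0[_IDX["ATM"]] = params.ATM_tot
    y0[_IDX["IKKg"]] = params.IKKg_tot
    y0[_IDX["TRAF6"]] = params.TRAF6_tot
    y0[_IDX["TAK1"]] = params.TAK1_tot
    return y0


def moiety_residuals(state: np.ndarray, params: ParameterSet) -> dict[str, float]:
    """Signed deviation of each conserved sum from its declared total."""
    y = np.asarray(state, dtype=float)
    return {
        total: float(sum(y[_IDX[s]] for s in members) - getattr(params, total))
        for total, members in MOIETIES.items()
    }


def state_to_dict(state: np.ndarray) -> dict[str, float]:
    return {name: float(state[i]) for i, name in enumerate(SPECIES)}


def species_index(name: str) -> int:
    """Index of a species in the canonical state vector."""
    try:
        return _IDX[name]
    except KeyError:
        raise KeyError(f"unknown species {name!r}; known: {', '.join(SPECIES)}") from None
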