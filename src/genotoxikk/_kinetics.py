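"""Low-level ODE right-hand side, flux vector and analytic Jacobian.

This module duplicates the kinetics of :mod:`genotoxikk.model` in a form the
stiff integrator can call cheaply (flat arrays, scalar arithmetic, optional
numba compilation).  :func:`genotoxikk.model.reaction_rates` remains the
readable reference; the test suite pins both paths to each other.

Parameter vector layout follows ``genotoxikk.parameters.PARAM_NAMES``; the
``drive`` argument carries the binding-site generation term
``k_DNAb * DNAb(t)``, which is the only explicit time dependence.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def flux_vector(y, p, drive):
    (bs_p, parp1, parp1dsb_b, parp1_b, parparp1_b, parparp1,
     bs_m, mrn, mrn_b, amrn_b, atm, patm,
     ikkg, sig, spikkg, traf6, at, att, tak1, _pikk) = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8], y[9],
        y[10], y[11], y[12], y[13], y[14], y[15], y[16], y[17], y[18], y[19])

    kon, koff, kr, koff2, vact, koff_act, kdepar = p[0], p[1], p[2], p[3], p[4], p[5], p[6]
    k1, k4, k2, k3, k5 = p[7], p[8], p[9], p[10], p[11]
    sfm_k1, sfm_k2, tm_k1, tm_k2, tm_k3 = p[12], p[13], p[14], p[15], p[16]
    km, km2, n_hill = p[17], p[18], p[19]
    ab = p[26]

    mrn_b_n = mrn_b ** n_hill if mrn_b > 0.0 else 0.0
    patm_n = patm ** n_hill if patm > 0.0 else 0.0

    v = np.empty(19)
    v[0] = drive
    v[1] = kon * parp1 * bs_p
    v[2] = koff * parp1dsb_b
    v[3] = kr * parp1 * parparp1_b
    v[4] = koff2 * parp1_b
    v[5] = vact * parp1dsb_b * ab
    v[6] = vact * parp1_b * ab
    v[7] = koff_act * parparp1_b
    v[8] = kdepar * parparp1
    v[9] = k1 * mrn * bs_m * mrn_b_n / (km + mrn_b_n)
    v[10] = k4 * mrn * bs_m
    v[11] = k2 * atm * mrn_b
    v[12] = k3 * amrn_b * patm_n / (km2 + patm_n)
    v[13] = k5 * amrn_b
    v[14] = sfm_k1 * parparp1 * patm * ikkg
    v[15] = sfm_k2 * sig
    v[16] = tm_k1 * patm * traf6
    v[17] = tm_k2 * at * tak1
    v[18] = tm_k3 * spikkg * att
    return v


@njit(cache=True)
def rhs(y, t, p, drive):
    v = flux_vector(y, p, drive)
    dy = np.empty(20)
    dy[0] = v[0] - v[1] + v[2]                                  # BS_P
    dy[1] = v[2] + v[4] + v[8] + v[15] - v[1] - v[3]            # PARP1
    dy[2] = v[1] - v[2] - v[5]                                  # PARP1DSB_b
    dy[3] = v[3] - v[4] - v[6]                                  # PARP1_b
    dy[4] = v[5] + v[6] - v[7]                                  # parPARP1_b
    dy[5] = v[7] - v[8] - v[14]                                 # parPARP1
    dy[6] = v[0] - v[9] - v[10]                                 # BS_M
    dy[7] = -v[9] - v[10]                                       # MRN
    dy[8] = v[9] + v[10] - v[11] + v[12] + v[13]                # MRN_b
    dy[9] = v[11] - v[12] - v[13]                               # AMRN_b
    dy[10] = -v[11]                                             # ATM
    dy[11] = v[12] + v[13] - v[14] + v[15] - v[16]              # pATM
    dy[12] = -v[14]                                             # IKKg
    dy[13] = v[14] - v[15]                                      # sig
    dy[14] = v[15] - v[18]                                      # spIKKg
    dy[15] = -v[16]                                             # TRAF6
    dy[16] = v[16] - v[17]                                      # AT
    dy[17] = v[17]                                              # ATT
    dy[18] = -v[17]                                             # TAK1
    dy[19] = v[18]                                              # pIKK
    return dy


@njit(cache=True)
def jacobian(y, t, p, drive):
    """Analytic Jacobian d(rhs)/dy, assembled from the flux derivatives."""
    bs_p, parp1, parp1dsb_b, parp1_b, parparp1_b, parparp1 = y[0], y[1], y[2], y[3], y[4], y[5]
    bs_m, mrn, mrn_b, amrn_b, atm, patm = y[6], y[7], y[8], y[9], y[10], y[11]
    ikkg, _sig, spikkg, traf6, at, att, tak1 = y[12], y[13], y[14], y[15], y[16], y[17], y[18]

    kon, koff, kr, koff2, vact, koff_act, kdepar = p[0], p[1], p[2], p[3], p[4], p[5], p[6]
    k1, k4, k2, k3, k5 = p[7], p[8], p[9], p[10], p[11]
    sfm_k1, sfm_k2, tm_k1, tm_k2, tm_k3 = p[12], p[13], p[14], p[15], p[16]
    km, km2, n_hill = p[17], p[18], p[19]
    ab = p[26]

    dv = np.zeros((19, 20))
    dv[1, 0] = kon * parp1
    dv[1, 1] = kon * bs_p
    dv[2, 2] = koff
    dv[3, 1] = kr * parparp1_b
    dv[3, 4] = kr * parp1
    dv[4, 3] = koff2
    dv[5, 2] = vact * ab
    dv[6, 3] = vact * ab
    dv[7, 4] = koff_act
    dv[8, 5] = kdepar

    if mrn_b > 0.0:
        u = mrn_b ** n_hill
        h = u / (km + u)
        hprime = km * n_hill * mrn_b ** (n_hill - 1.0) / (km + u) ** 2
    else:
        h = 0.0
        hprime = 0.0
    dv[9, 7] = k1 * bs_m * h
    dv[9, 6] = k1 * mrn * h
    dv[9, 8] = k1 * mrn * bs_m * hprime
    dv[10, 7] = k4 * bs_m
    dv[10, 6] = k4 * mrn
    dv[11, 10] = k2 * mrn_b
    dv[11, 8] = k2 * atm

    if patm > 0.0:
        w = patm ** n_hill
        g = w / (km2 + w)
        gprime = km2 * n_hill * patm ** (n_hill - 1.0) / (km2 + w) ** 2
    else:
        g = 0.0
        gprime = 0.0
    dv[12, 9] = k3 * g
    dv[12, 11] = k3 * amrn_b * gprime
    dv[13, 9] = k5

    dv[14, 5] = sfm_k1 * patm * ikkg
    dv[14, 11] = sfm_k1 * parparp1 * ikkg
    dv[14, 12] = sfm_k1 * parparp1 * patm
    dv[15, 13] = sfm_k2
    dv[16, 11] = tm_k1 * traf6
    dv[16, 15] = tm_k1 * patm
    dv[17, 16] = tm_k2 * tak1
    dv[17, 18] = tm_k2 * at
    dv[18, 14] = tm_k3 * att
    dv[18, 17] = tm_k3 * spikkg

    jac = np.zeros((20, 20))
    for j in range(20):
        jac[0, j] = -dv[1, j] + dv[2, j]
        jac[1, j] = dv[2, j] + dv[4, j] + dv[8, j] + dv[15, j] - dv[1, j] - dv[3, j]
        jac[2, j] = dv[1, j] - dv[2, j] - dv[5, j]
        jac[3, j] = dv[3, j] - dv[4, j] - dv[6, j]
        jac[4, j] = dv[5, j] + dv[6, j] - dv[7, j]
        jac[5, j] = dv[7, j] - dv[8, j] - dv[14, j]
        jac[6, j] = -dv[9, j] - dv[10, j]
        jac[7, j] = -dv[9, j] - dv[10, j]
        jac[8, j] = dv[9, j] + dv[10, j] - dv[11, j] + dv[12, j] + dv[13, j]
        jac[9, j] = dv[11, j] - dv[12, j] - dv[13, j]
        jac[10, j] = -dv[11, j]
        jac[11, j] = dv[12, j] + dv[13, j] - dv[14, j] + dv[15, j] - dv[16, j]
        jac[12, j] = -dv[14, j]
        jac[13, j] = dv[14, j] - dv[15, j]
        jac[14, j] = dv[15, j] - dv[18, j]
        jac[15, j] = -dv[16, j]
        jac[16, j] = dv[16, j] - dv[17, j]
        jac[17, j] = dv[17, j]
        jac[18, j] = -dv[17, j]
        jac[19, j] = dv[18, j]
    return jac
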