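"""Reaction-rate laws, ODE right-hand side, and conservation structure."""

import numpy as np
import pytest

import genotoxikk as gx
from genotoxikk import _kinetics
from genotoxikk.model import (MOIETIES, N_SPECIES, SPECIES, STOICHIOMETRY,
                              initial_state, moiety_residuals, ode_rhs,
                              reaction_rates, species_index)
from conftest import random_states


def oracle_rhs(state: dict, p: dict, drive: float) -> dict:
    """Independent re-implementation: each flux and signed sum transcribed
    separately from the rate laws, species by species."""
    n = p["n_hill"]
    v = {
        1: drive,
        2: p["kon"] * state["PARP1"] * state["BS_P"],
        3: p["koff"] * state["PARP1DSB_b"],
        4: p["kr"] * state["PARP1"] * state["parPARP1_b"],
        5: p["koff2"] * state["PARP1_b"],
        6: p["vact"] * state["PARP1DSB_b"] * p["AB"],
        7: p["vact"] * state["PARP1_b"] * p["AB"],
        8: p["koff_act"] * state["parPARP1_b"],
        9: p["kdepar"] * state["parPARP1"],
        10: p["k1"] * state["MRN"] * state["BS_M"] * state["MRN_b"] ** n
            / (p["km"] + state["MRN_b"] ** n),
        11: p["k4"] * state["MRN"] * state["BS_M"],
        12: p["k2"] * state["ATM"] * state["MRN_b"],
        13: p["k3"] * state["AMRN_b"] * state["pATM"] ** n
            / (p["km2"] + state["pATM"] ** n),
        14: p["k5"] * state["AMRN_b"],
        15: p["SFM_k1"] * state["parPARP1"] * state["pATM"] * state["IKKg"],
        16: p["SFM_k2"] * state["sig"],
        17: p["TM_k1"] * state["pATM"] * state["TRAF6"],
        18: p["TM_k2"] * state["AT"] * state["TAK1"],
        19: p["TM_k3"] * state["spIKKg"] * state["ATT"],
    }
    return {
        "BS_P": v[1] - v[2] + v[3],
        "PARP1": v[3] + v[5] + v[9] + v[16] - v[2] - v[4],
        "PARP1DSB_b": v[2] - v[3] - v[6],
        "PARP1_b": v[4] - v[5] - v[7],
        "parPARP1_b": v[6] + v[7] - v[8],
        "parPARP1": v[8] - v[9] - v[15],
        "BS_M": v[1] - v[10] - v[11],
        "MRN": -v[10] - v[11],
        "MRN_b": v[10] + v[11] - v[12] + v[13] + v[14],
        "AMRN_b": v[12] - v[13] - v[14],
        "ATM": -v[12],
        "pATM": v[13] + v[14] - v[15] + v[16] - v[17],
        "IKKg": -v[15],
        "sig": v[15] - v[16],
        "spIKKg": v[16] - v[19],
        "TRAF6": -v[17],
        "AT": v[17] - v[18],
        "ATT": v[18],
        "TAK1": -v[18],
        "pIKK": v[19],
    }


def test_rhs_matches_independent_oracle(bestfit):
    proto = gx.StimulusProtocol.from_dose(15.0)
    pdict = bestfit.as_dict()
    for i, y in enumerate(random_states(bestfit, 20)):
        t = 30.0 if i % 2 == 0 else 120.0  # during and after the pulse
        expected = oracle_rhs(dict(zip(SPECIES, y)), pdict, proto.k_dnab * proto.dnab(t))
        got = ode_rhs(y, bestfit, proto, t)
        np.testing.assert_allclose(got, [expected[s] for s in SPECIES],
                                   rtol=1e-12, atol=1e-12)


def test_fast_kinetics_path_matches_reference(bestfit):
    proto = gx.StimulusProtocol.from_dose(10.0)
    p = bestfit.as_array()
    for y in random_states(bestfit, 10, seed=1):
        ref_rates = reaction_rates(y, bestfit, proto, 10.0)
        np.testing.assert_allclose(
            _kinetics.flux_vector(y, p, proto.k_dnab), ref_rates, rtol=1e-13)
        np.testing.assert_allclose(
            _kinetics.rhs(y, 10.0, p, proto.k_dnab), STOICHIOMETRY @ ref_rates,
            rtol=1e-12, atol=1e-12)


def test_analytic_jacobian_matches_finite_differences(bestfit):
    proto = gx.StimulusProtocol.from_dose(10.0)
    p = bestfit.as_array()
    y = random_states(bestfit, 1, seed=2)[0]
    jac = _kinetics.jacobian(y, 0.0, p, proto.k_dnab)
    num = np.empty((N_SPECIES, N_SPECIES))
    for j in range(N_SPECIES):
        h = max(1e-6 * y[j], 1e-9)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        num[:, j] = (_kinetics.rhs(yp, 0.0, p, proto.k_dnab)
                     - _kinetics.rhs(ym, 0.0, p, proto.k_dnab)) / (2 * h)
    np.testing.assert_allclose(jac, num, rtol=2e-5, atol=1e-6)


@pytest.mark.parametrize("rate_r,expected", [(0.0, 0.0), (1.0, 70.0), (0.5, 35.0)])
def test_binding_site_rate(rate_r, expected):
    assert gx.compute_binding_site_rate(rate_r) == expected


def test_binding_site_rate_is_linear_and_rejects_negative():
    rng = np.random.default_rng(3)
    for r in rng.uniform(0, 10, 20):
        a = rng.uniform(0.1, 5)
        assert gx.compute_binding_site_rate(a * r) == pytest.approx(
            a * gx.compute_binding_site_rate(r))
    with pytest.raises(ValueError):
        gx.compute_binding_site_rate(-0.1)


def test_signalosome_flux_is_direct_product(bestfit):
    y = np.zeros(N_SPECIES)
    y[species_index("parPARP1")] = 10.0
    y[species_index("pATM")] = 20.0
    y[species_index("IKKg")] = 30.0
    params = bestfit.replace(SFM_k1=0.01)
    v = reaction_rates(y, params, gx.StimulusProtocol.from_dose(1.0), 1e4)
    assert v[14] == pytest.approx(60.0)


def test_atm_feedback_half_saturation(bestfit):
    y = np.zeros(N_SPECIES)
    y[species_index("AMRN_b")] = 5.0
    y[species_index("pATM")] = np.sqrt(bestfit.km2)  # pATM^2 == km2
    v = reaction_rates(y, bestfit, gx.StimulusProtocol.from_dose(1.0), 1e4)
    assert v[12] == pytest.approx(0.5 * bestfit.k3 * 5.0)


def test_catalytically_dead_variant_blocks_parylation_fluxes(bestfit):
    y = np.zeros(N_SPECIES)
    y[species_index("PARP1DSB_b")] = 50.0
    y[species_index("PARP1_b")] = 70.0
    v = reaction_rates(y, bestfit.replace(AB=0.0), gx.StimulusProtocol.from_dose(1.0), 10.0)
    assert v[5] == 0.0 and v[6] == 0.0
    v_wt = reaction_rates(y, bestfit, gx.StimulusProtocol.from_dose(1.0), 10.0)
    assert v_wt[5] > 0 and v_wt[6] > 0


def test_moiety_rows_are_left_null_vectors_of_stoichiometry():
    # conservation is a structural property: each moiety's indicator vector
    # annihilates the stoichiometric matrix exactly
    for members in MOIETIES.values():
        ell = np.zeros(N_SPECIES)
        for s in members:
            ell[species_index(s)] = 1.0
        np.testing.assert_array_equal(ell @ STOICHIOMETRY, np.zeros(19))


def test_initial_state_is_rest_point_with_zero_residuals(bestfit):
    y0 = initial_state(bestfit)
    res = moiety_residuals(y0, bestfit)
    assert all(v == 0.0 for v in res.values())
    proto = gx.StimulusProtocol.from_dose(0.0)
    np.testing.assert_array_equal(ode_rhs(y0, bestfit, proto, 100.0), np.zeros(N_SPECIES))


def test_parameter_validation():
    with pytest.raises(ValueError):
        gx.best_fit().replace(kon=-1.0)
    with pytest.raises(ValueError):
        gx.best_fit().replace(AB=0.5)
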