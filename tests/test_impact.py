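"""Time-resolved impact fractions: normalisation, oracle equivalence,
dominance labels, flux AUC and cumulative production."""

import numpy as np
import pytest

import genotoxikk as gx
from genotoxikk.impact import (IKK_ACTIVATION, SIGNALOSOME_FORMATION, FluxSpec,
                               ImpactFractionSeries, dominant_component,
                               impact_fractions, omega_from_rates)


# --- closed-form toy: three independent exponentials -----------------------

def test_omega_matches_closed_form_for_exponential_toy():
    """x=e^{at}, y=e^{bt}, z=e^{ct}: relative derivatives are the constants
    a, b, c, so omega_i = r_i / (|a|+|b|+|c|) exactly, at every time."""
    a, b, c = 0.7, -0.3, 0.05
    t = np.linspace(0.1, 10.0, 57)
    comps = np.column_stack([np.exp(a * t), 2.0 * np.exp(b * t), 0.5 * np.exp(c * t)])
    derivs = comps * np.array([a, b, c])
    omega, valid = omega_from_rates(comps, derivs)
    assert valid.all()
    expected = np.array([a, b, c]) / (abs(a) + abs(b) + abs(c))
    np.testing.assert_allclose(omega, np.broadcast_to(expected, omega.shape),
                               rtol=1e-10, atol=1e-10)


def test_omega_symmetry_and_single_active_component():
    comps = np.array([[4.0, 5.0, 6.0]])
    # equal positive relative derivatives -> equal thirds
    omega, _ = omega_from_rates(comps, comps * 0.2)
    np.testing.assert_allclose(omega, 1.0 / 3.0)
    # only x changing -> (1, 0, 0)
    omega, _ = omega_from_rates(comps, np.array([[0.8, 0.0, 0.0]]))
    np.testing.assert_allclose(omega[0], [1.0, 0.0, 0.0])


def test_absolute_fractions_sum_to_one_on_trajectory(traj15):
    for spec in (SIGNALOSOME_FORMATION, IKK_ACTIVATION):
        series = impact_fractions(traj15, spec)
        sums = np.abs(series.omega[series.valid]).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)
        assert np.nanmax(np.abs(series.omega)) <= 1.0 + 1e-12
        assert series.valid.any()


def test_omega_sign_matches_component_derivative(traj15, bestfit):
    series = impact_fractions(traj15, SIGNALOSOME_FORMATION)
    p = bestfit.as_array()
    idx = [gx.model.species_index(s) for s in series.components]
    for i in np.nonzero(series.valid)[0][::50]:
        drive = traj15.protocol.k_dnab * traj15.protocol.dnab(traj15.times[i])
        dy = gx._kinetics.rhs(traj15.states[i], traj15.times[i], p, drive)[idx]
        assert np.all(np.sign(series.omega[i]) == np.sign(dy))


def test_log_derivative_identity_against_flux_finite_differences(traj15):
    """(dv/dt)/v equals the sum of the component relative derivatives."""
    series = impact_fractions(traj15, SIGNALOSOME_FORMATION)
    t, v = traj15.times, series.flux
    # centred differences on the interior of the densely sampled first hour
    sel = np.arange(300, 3000, 100)
    dv = (v[sel + 1] - v[sel - 1]) / (t[sel + 1] - t[sel - 1])
    lhs = dv / v[sel]
    idx = [gx.model.species_index(s) for s in series.components]
    p = traj15.params.as_array()
    rhs = []
    for i in sel:
        dy = gx._kinetics.rhs(traj15.states[i], t[i], p, 0.0)[idx]
        rhs.append(np.sum(dy / traj15.states[i][idx]))
    np.testing.assert_allclose(lhs, rhs, rtol=2e-3, atol=1e-6)


def test_impact_fractions_mask_initial_zero_components(traj15):
    series = impact_fractions(traj15, SIGNALOSOME_FORMATION)
    assert not series.valid[0]  # parPARP = pATM = 0 at t = 0
    assert np.all(np.isnan(series.omega[0]))


def test_flux_spec_rejects_non_product_forms(traj15):
    with pytest.raises(ValueError):
        # v13 is a Hill flux, not the product of k3 and these species
        impact_fractions(traj15, FluxSpec("k3", ("AMRN_b", "pATM"), "v13"))
    with pytest.raises(ValueError):
        FluxSpec("SFM_k1", ("parPARP1",), "v15")  # too few components
    with pytest.raises(KeyError):
        FluxSpec("SFM_k1", ("parPARP1", "nosuch"), "v15")


def _series(omega_rows, components=("x", "y", "z")):
    omega = np.asarray(omega_rows, dtype=float)
    n = omega.shape[0]
    return ImpactFractionSeries(
        times=np.arange(n, dtype=float), components=tuple(components),
        omega=omega, flux=np.ones(n), valid=np.ones(n, bool), flux_id="v15")


def test_dominant_component_threshold_logic():
    series = _series([[0.6, -0.3, 0.1], [0.45, -0.45, 0.10]])
    assert dominant_component(series) == ["x", None]
    with pytest.raises(ValueError):
        dominant_component(series, threshold=0.0)


def test_dominance_switch_from_att_to_spikkg_at_fifteen_gray(traj15):
    """At full activation the IKK-activation flux is first driven by the
    rising cytoplasmic ATM-TRAF6-TAK1 complex, later controlled by the
    declining pool of modified IKKγ."""
    series = impact_fractions(traj15, IKK_ACTIVATION)
    labels = np.array([lab or "none" for lab in dominant_component(series)])
    t_min = traj15.times / 60.0
    rise = series.flux.argmax()
    att_window = (t_min > 8) & (t_min < t_min[rise])
    assert (labels[att_window] == "ATT").mean() > 0.8
    late = (t_min > 60) & (t_min < 180)
    assert (labels[late] == "spIKKg").mean() > 0.9
    # ATT dominance precedes spIKKg dominance
    att_times = t_min[labels == "ATT"]
    sp_times = t_min[labels == "spIKKg"]
    assert np.median(att_times) < np.median(sp_times)


def test_flux_auc_zero_without_stimulus(bestfit):
    traj = gx.simulate(bestfit, gx.StimulusProtocol.from_dose(0.0), 600.0)
    assert gx.flux_auc(traj, "v15") == 0.0


def test_flux_auc_window_validation(traj15):
    with pytest.raises(ValueError):
        gx.flux_auc(traj15, "v15", window=(0.0, 1e7))
    full = gx.flux_auc(traj15, "v15")
    head = gx.flux_auc(traj15, "v15", window=(0.0, 600.0))
    tail = gx.flux_auc(traj15, "v15", window=(600.0, traj15.times[-1]))
    assert head + tail == pytest.approx(full, rel=1e-9)


def test_cumulative_parparp_production(bestfit, traj15):
    produced = gx.cumulative_production(traj15, "parPARP1")
    # recycling only adds: cumulative production dominates any instantaneous level
    assert produced >= traj15.species("parPARP1").max()
    # catalytically dead PARP-1 produces nothing
    dead = gx.simulate(bestfit.replace(AB=0.0), gx.StimulusProtocol.from_dose(15.0), 3600.0)
    assert gx.cumulative_production(dead, "parPARP1") == pytest.approx(0.0, abs=1e-6)


def test_cumulative_parparp_production_increases_with_dose(bestfit):
    totals = []
    for dose in (2.0, 10.0, 40.0):
        traj = gx.simulate(bestfit, gx.StimulusProtocol.from_dose(dose), 21600.0)
        totals.append(gx.cumulative_production(traj, "parPARP1"))
    assert totals[0] < totals[1] < totals[2]


def test_cumulative_production_requires_unique_producer(traj15):
    with pytest.raises(ValueError, match="v13"):
        gx.cumulative_production(traj15, "pATM")
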