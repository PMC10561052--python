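"""Objective function, multi-start fitting, profile likelihood."""

import numpy as np
import pytest

import genotoxikk as gx
from genotoxikk.inference import (FAILURE_COST, fit, objective,
                                  predict_observables, profile_cost_at,
                                  profile_likelihood)
from genotoxikk.observables import DEFAULT_OBSERVABLES
from genotoxikk.synthetic import AssayDesign, generate_dataset

CHEAP = AssayDesign("cheap_mrn", "mrn_recruitment", dose=2.0,
                    times=(0.0, 120.0, 300.0, 600.0, 1200.0, 1800.0),
                    noise="gaussian", sigma=0.05)
EMSA = AssayDesign("cheap_emsa", "nfkb_emsa", dose=40.0,
                   times=tuple(np.linspace(0, 10800, 7)), noise="lognormal",
                   sigma=0.1)


@pytest.fixture(scope="module")
def noiseless(bestfit):
    designs = [AssayDesign(**{**d.__dict__, "sigma": 0.0}) for d in (CHEAP, EMSA)]
    return [generate_dataset(bestfit, d, seed=i) for i, d in enumerate(designs)]


def test_predictions_are_affine_in_scale(bestfit, traj15):
    obs = DEFAULT_OBSERVABLES["nfkb_emsa"]
    ds = generate_dataset(bestfit, EMSA, seed=0)
    base = predict_observables(traj15, ds, obs)
    double = predict_observables(traj15, ds, obs, scale=2.0)
    np.testing.assert_allclose(double, 2.0 * base)
    shifted = predict_observables(traj15, ds, obs, offset=5.0)
    np.testing.assert_allclose(shifted, base + 5.0)


def test_prediction_outside_span_raises(bestfit):
    traj = gx.simulate(bestfit, gx.StimulusProtocol.from_dose(2.0), 600.0)
    obs = DEFAULT_OBSERVABLES["nfkb_emsa"]
    with pytest.raises(ValueError):
        obs.predict(traj, np.array([1200.0]))


def test_objective_zero_at_truth_and_larger_elsewhere(bestfit, noiseless):
    assert objective(bestfit, noiseless) == pytest.approx(0.0, abs=1e-8)
    # scale profiling absorbs pure amplitude changes, so perturb a
    # timing-determining constant
    worse = objective(bestfit.scaled(("kdepar",), 5.0), noiseless)
    assert worse > 1e-6


def test_objective_adds_over_datasets(bestfit, noiseless):
    ds = generate_dataset(bestfit, CHEAP, seed=3)
    both = objective(bestfit, [ds] + noiseless)
    alone = objective(bestfit, [ds])
    rest = objective(bestfit, noiseless)
    assert both == pytest.approx(alone + rest, rel=1e-9)


def test_objective_invariant_to_data_units(bestfit):
    ds = generate_dataset(bestfit, CHEAP, seed=4)
    rescaled = gx.datasets.ExperimentalDataset(
        dataset_id=ds.dataset_id, observable_id=ds.observable_id,
        protocol=ds.protocol, times=ds.times, values=1e3 * ds.values,
        sigmas=1e3 * ds.sigmas, ab=ds.ab)
    a = objective(bestfit, [ds])
    b = objective(bestfit, [rescaled])
    assert a == pytest.approx(b, rel=1e-9)


def test_chi_square_expectation_with_known_noise(bestfit):
    """At the true parameters the expected cost equals the residual count."""
    rng = np.random.default_rng(123)
    costs = []
    for _ in range(100):
        ds = generate_dataset(bestfit, CHEAP, seed=rng)
        costs.append(objective(bestfit, [ds]))
    n = len(CHEAP.times)
    # scale profiling absorbs about one degree of freedom
    assert np.mean(costs) / n == pytest.approx(1.0, abs=0.25)


def test_failed_simulation_returns_sentinel(bestfit, noiseless):
    # a wildly stiff parameter point may fail; fabricate failure via an
    # unsatisfiable horizon by monkeypatching is brittle -- instead check the
    # sentinel contract directly on an extreme parameter point
    extreme = bestfit.replace(kon=1e3, kr=1e-3, vact=1e3)
    cost = objective(extreme, noiseless)
    assert np.isfinite(cost)
    assert cost <= FAILURE_COST


def test_fit_is_deterministic_and_beats_its_starts(bestfit, noiseless):
    kwargs = dict(base=bestfit.scaled(("vact",), 2.0), free=("vact",),
                  n_starts=3, seed=9, max_nfev=25)
    a = fit(noiseless, **kwargs)
    b = fit(noiseless, **kwargs)
    assert a.log10_values == b.log10_values and a.cost == b.cost
    start_costs = [r["cost"] for r in a.starts]
    assert a.cost <= min(start_costs) + 1e-12


def test_fit_recovers_single_parameter_from_noiseless_data(bestfit, noiseless):
    result = fit(noiseless, base=bestfit.scaled(("kdepar",), 3.0),
                 free=("kdepar",), n_starts=4, seed=1, max_nfev=40)
    assert 10 ** result.log10_values["kdepar"] == pytest.approx(
        bestfit.kdepar, rel=0.05)
    assert result.cost < 1.0


def test_profile_zero_at_optimum(bestfit, noiseless):
    result = fit(noiseless, base=bestfit, free=("vact", "kdepar"),
                 n_starts=1, seed=0, max_nfev=30)
    c = profile_cost_at(result, noiseless, "vact",
                        result.log10_values["vact"], max_nfev=20)
    assert c <= result.cost + 1e-6


def test_product_degenerate_pair_has_flat_profile(bestfit):
    """k4 and MRN_tot enter the observable kinetics only through their
    product when the feedback path is negligible and the amplitude is
    scale-profiled, so neither has a finite confidence interval."""
    degenerate = bestfit.replace(k1=1e-9)
    design = AssayDesign("mrn_flat", "mrn_recruitment", dose=2.0,
                         times=(0.0, 200.0, 600.0, 1400.0, 2600.0, 4000.0),
                         noise="gaussian", sigma=0.0)
    ds = generate_dataset(degenerate, design, seed=0)
    result = fit([ds], base=degenerate, free=("k4", "MRN_tot"),
                 n_starts=1, seed=0, max_nfev=25)
    prof = profile_likelihood(result, [ds], "MRN_tot", n_steps=4, step=0.5,
                              max_nfev=25)
    assert prof.costs.max() - prof.best_cost < prof.threshold
    assert prof.upper is None and prof.lower is None
    assert prof.classification == "unidentifiable"


def test_profile_detects_identifiable_parameter(bestfit):
    """The signalosome co-IP time course pins the dissociation rate of
    PARylated DNA-bound PARP-1 from both sides: it sets both the rise and
    the decay timescale of the complex."""
    sig = AssayDesign("sig80", "signalosome", dose=80.0,
                      times=tuple(60.0 * np.array(
                          [0, 2, 5, 10, 15, 20, 30, 45, 60, 90, 120])),
                      noise="lognormal", sigma=0.1)
    noisy = [generate_dataset(bestfit, sig, seed=31)]
    result = fit(noisy, base=bestfit, free=("kdepar", "koff_act"),
                 n_starts=1, seed=0, max_nfev=40)
    prof = profile_likelihood(result, noisy, "koff_act", n_steps=6, step=0.3,
                              max_nfev=25)
    assert prof.classification == "two-sided"
    assert prof.lower < result.log10_values["koff_act"] < prof.upper
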