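# genotoxikk

Dynamics and inference for DNA damage-induced IKK/NF-κB activation.

Ionising radiation creates DNA double-strand breaks; the sensors PARP-1 and
the MRN complex detect them, a nuclear *signalosome* of PARylated PARP-1,
phosphorylated ATM and IKKγ (NEMO) posttranslationally modifies IKKγ, and
in the cytoplasm the ATM–TRAF6–TAK1 complex together with modified IKKγ
irreversibly activates the IKK complex — the direct upstream switch of
NF-κB. Because NF-κB is anti-apoptotic, this pathway can blunt
radio-/chemotherapy, and its dose dependence matters for interpreting both
bench and clinical studies.

`genotoxikk` implements this pathway as a 20-species mass-action/Hill ODE
model (units: molecules and seconds) with an irradiation stimulus of
35 DSB/Gy × 2 binding sites, plus the analysis layer around it:

- **simulation**: stiff integration (LSODA, analytic Jacobian), stimulated
  steady states, dose–response curves;
- **impact fractions**: for a product-form flux `v = k·x·y·z`, the
  normalised relative rate of change of each component,
  `ω_c = ((dc/dt)/c) / Σ_k |(dk/dt)/k|`, so that `Σ|ω| = 1` — a
  time-resolved decomposition of what drives a flux up or down, with
  dominance labelling at `|ω| > 0.5`;
- **sensitivity / inhibition scans**: finite 90% parameter reductions,
  `sc = (pIKK*_perturbed − pIKK*)/pIKK*`, and efficiency × dose inhibition
  grids for ATM activation (k3 & k5) and PARP-1 auto-modification (vact);
- **inference**: multi-start bounded maximum likelihood in log10 space with
  analytically profiled scale factors, and profile-likelihood
  identifiability with open-interval classification;
- **synthetic data**: seeded generators emulating the seven assay families
  used to constrain such models (recruitment fluorescence, pATM blots,
  signalosome co-IP, TRAF6 blots, NF-κB EMSA), so the whole inference loop
  is testable offline.

The bundled reference parameter set (`genotoxikk.best_fit()`) is a
synthetic calibrated stand-in, documented in `docs/methods.md`; measured
totals (PARP-1 1.9×10⁵, ATM 7×10³, IKKγ 9.8×10⁴ molecules) are fixed at
reported values.

## Worked example

```python
import genotoxikk as gx

params = gx.best_fit()
proto = gx.StimulusProtocol.from_dose(15.0)        # 15 Gy over 60 s
traj = gx.simulate(params, proto, horizon=42_000)  # 700 min

print(f"signalosome flux AUC: {gx.flux_auc(traj, 'v15'):,.0f} molecules")
ss = gx.stimulated_steady_state(params, proto)
print(f"steady-state activated IKK: {ss.pikk:,.0f} of {params.IKKg_tot:,.0f}")

import numpy as np
series = gx.impact_fractions(traj, gx.IKK_ACTIVATION)
labels = np.array([l or "none" for l in gx.dominant_component(series)])
peak = series.flux.argmax()
switch = traj.times[peak + np.argmax(labels[peak:] == "spIKKg")]
print(f"dominant driver switches ATT -> spIKKg at {switch/60:.0f} min")
```

prints

```
signalosome flux AUC: 98,001 molecules
steady-state activated IKK: 98,000 of 98,000
dominant driver switches ATT -> spIKKg at 25 min
```

— at 15 Gy every IKKγ molecule is eventually modified and integrated into
an active IKK complex (the flux AUC *is* the number of modified IKKγ, and
it saturates the IKKγ pool: full activation), and the early rise of IKK
activity is controlled by the cytoplasmic ATM–TRAF6–TAK1 complex before
control hands over to the declining supply of modified IKKγ.

From the shell:

```sh
genotoxikk dose-response --doses 1:100 --out dr.csv
genotoxikk impact --flux v15 --dose 15 --out impact.csv
genotoxikk sensitivity --reduction 0.9 --doses 1:100:1 --out sens.csv
genotoxikk synth --seed 1 --out suite.csv
genotoxikk fit --data suite.csv --starts 20 --seed 1 --out fit.yaml
```

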