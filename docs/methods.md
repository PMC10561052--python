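# Methods

## The model

`genotoxikk` implements a deterministic kinetic model of IKK/NF-κB
activation by DNA double-strand breaks as a system of 20 coupled ODEs in
molecule numbers (units: molecules, seconds). The network has two signalling
hubs:

1. **Signalosome formation (nuclear).** Irradiation at dose rate *r* (Gy/s)
   generates binding sites for the two damage sensors at
   `k_DNAb = r · 35 DSB/Gy · 2 sites/DSB` while the indicator `DNAb(t)` is 1
   (during the pulse). PARP-1 binds sites directly (`kon`/`koff`), or is
   recruited by PARylated DNA-bound PARP-1 (`kr`/`koff2`); catalytically
   active PARP-1 (switch `AB = 1`; the E988K variant has `AB = 0`)
   auto-modifies at `vact`, dissociates at `koff_act`, and free PARylated
   PARP-1 is dePARylated at `kdepar`. The MRN complex occupies its sites
   with a Hill-type positive feedback (`k1`, `k4`, `km`), recruits ATM
   (`k2`) and activates it with a second Hill feedback (`k3`, `k5`, `km2`;
   Hill coefficient 2 for both, reflecting dimeric ATM autoactivation).
   PARylated PARP-1, phosphorylated ATM and IKKγ form the signalosome at
   the trimolecular rate `SFM_k1·parPARP1·pATM·IKKγ` (flux v15); its
   disassembly (`SFM_k2`) releases sumoylated/phosphorylated IKKγ.
2. **IKK activation (cytoplasmic).** pATM polyubiquitinates TRAF6
   (`TM_k1`), TAK1 joins (`TM_k2`) to give the catalytic ATT complex, and
   spIKKγ is irreversibly converted into activated IKK complex at
   `TM_k3·spIKKγ·ATT` (flux v19) — a coherent feedforward loop: both
   branches descend from pATM. pIKK is the model readout (a validated proxy
   for NF-κB activity).

Six moiety totals are conserved exactly (PARP-1, MRN, ATM, IKKγ, TRAF6,
TAK1); the implementation computes the right-hand side as a stoichiometric
matrix times the 19-flux vector, so the conservation laws hold to machine
precision at the level of the vector field, and to integrator tolerance
along trajectories. Because the conversion of spIKKγ by ATT is catalytic
and irreversible, the time integral of the signalosome-formation flux
equals the stimulated steady-state level of activated IKK complex — the
bookkeeping identity several analyses and tests rely on.

The Hill denominators are written literally as `km + x^n`, so `km`/`km2`
carry units of molecules^n; their fitting bounds are wider than the generic
rate-constant box for that reason.

## Reference parameter set

`genotoxikk.best_fit()` loads
`src/genotoxikk/data/bestfit_synthetic.yaml`, a **synthetic calibrated
stand-in** for a full data-driven fit (no externally fitted parameter set
is bundled). Quantities with reported values are fixed: `PARP1_tot = 1.9e5`,
`ATM_tot = 7e3`, `IKKg_tot = 9.8e4` molecules, `n_hill = 2`, and `kdepar`
inside the published PARylated-PARP-1 half-life range. The free kinetic
constants were calibrated once, before the test suite was frozen, so the
model reproduces the reference behaviour:

- full IKK-complex activation (0.99 of the maximal response) first reached
  at 13 Gy on a 0.5 Gy dose scan;
- signalosome-flux AUC of ≈98,000 molecules at 15 Gy, dropping to ≈59,000
  when ATM activation (`k3` & `k5`) is reduced by 90%;
- flux extinction (below 0.1% of peak) near 190–205 min and pIKK settling
  (99% of its steady state) near 180–200 min at 15 Gy;
- a 90%-ATM-inhibition efficacy boundary (reduction falls below 5%) at
  25 Gy;
- sensitivity orderings: `PARP1_tot`, `kr`, `vact` are the strongest
  negative coefficients at every dose, `koff2`/`koff_act` are positive at
  sub-saturating doses.

Mechanistically the calibration puts the PARP-1 recruitment cascade
(`PARP1 → PARP1_b → parPARP1_b`, seeded by site-bound PARylation events)
**near criticality**: its branching ratio
`kr·PARP1_tot·vact / ((koff2+vact)·koff_act) ≈ 0.994`, so every damage site
is amplified ~150-fold into PARylated PARP-1 production. This is what makes
the pathway output exquisitely sensitive to `kr`, `vact` and `PARP1_tot`
(and positively sensitive to the dissociation constants, whose reduction
pushes the cascade supercritical), and it reproduces the high cumulative
turnover of PARylated PARP-1 from a small instantaneous pool.

**Known limitation.** One reported behaviour is *not* met by this fixture:
99% inhibition of ATM activation at 80 Gy still lowers the steady-state
pIKK by ~31% (the reference behaviour is <5%). Within this topology the
only quantities that can offset slower ATM activation at high dose are the
PARylated-PARP reservoir (∝ dose) and its lifetime, and near criticality
the reservoir at high dose is *shorter*-lived (free-PARP-1 depletion lowers
the branching ratio), so a tenfold deeper inhibition cannot be fully
compensated by a 5.3-fold larger reservoir. The 90%-inhibition phenotypes
are reproduced quantitatively. The corresponding acceptance test is left
failing rather than weakened. A second deliberate deviation from typical
laser-microirradiation data: with the calibrated `kon`, PARP-1 site
occupancy equilibrates over minutes rather than seconds; the synthetic
recruitment datasets are generated from the same fixture, so the inference
loop remains exactly self-consistent.

## Simulation

Integration uses LSODA (via `scipy.integrate.odeint`) with an analytic
Jacobian, relative tolerance 1e-8 and absolute tolerance 1e-6 molecules,
split at the stimulus off-time so the discontinuity in the binding-site
generation term is never stepped across. The optional numba JIT compiles
the flux/RHS/Jacobian kernels (~3 s once per environment); a pure-NumPy
fallback keeps results identical. The dense default output grid is 1 s over
the first hour and geometric afterwards — needed for accurate trapezoidal
flux AUCs. Small negative excursions within solver tolerance are clipped to
zero; larger ones raise.

Steady states are detected by integrating past the pulse over a
geometrically growing checkpoint sequence until
`max_i |dx_i/dt| / max(x_i, 1) < 1e-9 s⁻¹` (hard horizon 1e6 s; hitting the
horizon returns the state flagged as unconverged). The dose→protocol
convention is a 60 s pulse at constant rate (`rate_r = dose/60`), both
overridable; microirradiation protocols specify `k_DNAb` directly.

## Impact fractions

For a mass-action product flux `v = k·x·y(·z)` the log-derivative identity
`(dv/dt)/v = Σ (dc/dt)/c` motivates the time-resolved impact fraction
`ω_c = ((dc/dt)/c) / Σ_k |(dk/dt)/k|`; absolute fractions sum to one.
Derivatives are taken analytically from the ODE right-hand side at stored
states (no finite differencing). Times where a component is below 1e-6
molecules (e.g. t = 0) are masked invalid rather than extrapolated. The
dominance label at threshold 0.5 (the conventional choice; at or above 0.5
at most one component can qualify) identifies which component controls the
flux change. Hill-type fluxes are rejected: the decomposition is exact only
for products.

## Sensitivity and inhibition scans

The sensitivity coefficient is the relative change of steady-state pIKK
under a finite 90% parameter reduction; −1 means complete suppression and
positive values are unbounded. Reducing a conserved total rescales the
corresponding initial free-species abundance with it (the initial state is
constructed from the totals), the only self-consistent reading. Inhibition
grids map an efficiency *e* to multiplication of the target parameters by
1−e; ATM-activation inhibition targets `k3` & `k5` simultaneously,
PARylation inhibition targets `vact`. "Strongly reduce" is operationalised
in tests as ≥50% reduction of pIKK*.

## Inference

The objective is weighted least squares (twice the negative Gaussian
log-likelihood up to constants); per-dataset scale factors are profiled
analytically by weighted regression at every evaluation, which is exactly
equivalent to optimising them but far cheaper, and keeps the objective
invariant under changes of a dataset's arbitrary units. Datasets without
per-point errors contribute `n·log(SSR/n)` (noise level profiled
analytically). Kinetic parameters are handled in log10 space inside the
fitting box (generic [−10, 3]; `kdepar` [−4, 0]; totals [2, 7]; Hill
constants widened to [−10, 8] for their molecules² units). Multi-start
fitting draws seeded Latin-hypercube starts and refines each with bounded
trust-region least squares; simulation failures return a large sentinel
cost so optimisers retreat. Profile likelihoods re-optimise the remaining
free parameters while one parameter is stepped outward from the optimum
(warm-started), with the pointwise 95% threshold Δcost = 3.84 by default;
a confidence limit that runs into the fitting box before crossing the
threshold is reported as open on that side.

## Synthetic data

The generator emulates the quantified output of seven assay families
(PARP-1 recruitment after microirradiation for wild type and E988K, MRN/ATM
recruitment, nuclear and cytoplasmic pATM blots, signalosome co-IP, TRAF6
complex blots at 30 and 40 Gy, NF-κB EMSA) at the value level — never
images. Band-intensity readouts carry multiplicative log-normal noise
(σ_log = 0.1 by default; intensities are positive and ratio-normalised),
fluorescence traces additive Gaussian noise (relative σ = 0.05). Each
dataset draws a scale factor centring values on order one and records its
ground truth. The microirradiation designs use a fixed binding-site rate of
30 sites/s for 10 s, standing in for the fitted-rate convention of
dose-unknown laser damage. What passing tests show is internal consistency
of the full generate→fit→profile loop under the declared noise model; they
do not certify the noise structure of real blots, which is unknown.

The parameter-recovery experiment (20 replicates, 6 free parameters, 20
starts each) draws its starts from a prior box of ±1.25 decades around the
nominal values — the realistic scenario of refitting around literature
values. A global search over the full 13-decade box is out of reach of any
minutes-scale budget and, with capped local optimisation, stalls in remote
basins that make coverage meaningless. Coverage is assessed by the profile
cost at the true value against the 3.84 threshold, pooled over
(parameter, replicate) pairs.

## Numerical and design choices, in brief

- RHS = stoichiometry × fluxes: flux consistency and conservation are
  structural, not emergent.
- The initial condition is the unstimulated rest state (all mass in free
  PARP1, MRN, ATM, IKKγ, TRAF6, TAK1) — an exact fixed point without
  stimulus.
- Quadratures are trapezoidal on the dense grid; a grid-refinement test
  guards convergence.
- Problem sizes in the test suite (dose subsets, 700-min horizons, 20×20
  recovery design at solver rtol 1e-5) are chosen so the full suite runs in
  minutes on one core while every check retains its discriminating power.
- No SBML import: the YAML parameter table is the canonical fixture format.
- No stochastic simulation, no DNA-repair/damage-decay process (binding
  sites persist), no explicit PIASy/cIAP1/LUBAC species, no downstream
  IκB/NF-κB translocation dynamics — pIKK is the readout.
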