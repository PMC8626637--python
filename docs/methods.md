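# Methods

## Scope and model overview

`fetalkp` predicts the fetal-to-maternal unbound exposure ratio K_p,uu of
drugs that cross the human placenta passively and are returned to the
maternal circulation by apically localized efflux transporters
(P-glycoprotein as the model transporter). Two routes to K_p,uu are
implemented and meant to be compared:

* **in vitro (ER-REF)**: K_p,uu = 1/(1 + REF·ER_P-gp), from Transwell efflux
  ratios and proteomic transporter abundances;
* **in vivo (PBPK fit)**: K_p,uu from a maternal-fetal PBPK model whose
  placental efflux clearance is fitted to observed UV/MP concentration
  ratios.

Both rest on the same steady-state mass balance: with fetal elimination
negligible, the unbound fetal/maternal concentration ratio equals
CL_entry/(CL_entry + CL_exit,active), so only the *ratio* of efflux to
passive clearance matters, not their absolute magnitudes (until a perfusion
cap engages).

## Transwell reduction

Assumptions and conventions:

* Receiver withdrawals (100 µl, replaced with blank buffer) dilute the
  receiver; the cumulative-amount estimator adds back the withdrawn mass:
  `cA_k = V_R·C_k + Σ_{j<k} v_j·C_j`. Omitting this correction biases
  P_app low — a property asserted against the event-driven oracle.
* The donor-exposure denominator is the trapezoid AUC of the measured donor
  concentrations over the run, not `C_D(0)·T`; this corrects for donor
  depletion. Donor withdrawals (10 µl of 500–1000 µl) change the donor
  volume; the oracle tracks this exactly, the estimator ignores it (≤ 2%
  effect at protocol volumes).
* P_app is computed from the final cumulative amount over the full-interval
  donor AUC (the cumulative form); a slope-regression alternative
  (`method="slope"`) is available for linearity diagnostics only.
* Triplicate wells are averaged at the concentration level within an
  experiment before any ER arithmetic; experiment-level replicates are never
  pooled before ER, because transporter abundance differs between
  experiments and each ER is paired with its own abundance.
* Insert area defaults to 1.12 cm² (standard 12-well insert) and is
  configurable; units are minutes/µM/ml internally, cm/s only at the P_app
  boundary.
* QC: Lucifer yellow P_app ≥ 2·10⁻⁶ cm/s fails the monolayer; positive
  control ER ≤ 7 fails transporter activity. Missing QC data does not fail
  an experiment but leaves the flag unset.

## ER-REF scaling

* REF = in vivo abundance / in vitro abundance, both per mg total homogenate
  protein, experiment-matched on the in vitro side.
* Point estimate: arithmetic mean of per-experiment K_p,uu values. A second
  estimator — K_p,uu of (mean ER × REF of mean abundance) — is always
  reported (`point_kpuu_pooled`); the two differ when ER and abundance
  co-vary across experiments and neither dominates on first principles.
* Uncertainty: the CI90 is a seeded Monte-Carlo propagation with
  ER_P-gp ~ Normal(mean, sd) truncated at 0 and both abundances ~ Normal
  truncated at a small positive floor, all independent. This pooled-variance
  design is reproducible, assumption-explicit, and degenerates to the point
  estimate at zero variance. It treats experiment-to-experiment spread as
  random; with n = 4 experiments the interval is indicative, not exact.
* A negative ER_P-gp (noise around zero for a non-substrate) is clamped to 0
  by default (K_p,uu = 1) and can be made a hard error.

## Maternal-fetal PBPK model

State (amounts, mg): gut depot, maternal central, placenta, fetus, plus a
cumulative-elimination bookkeeping state.

* Absorption: first-order `ka` after lag `tlag`; bioavailability is applied
  to the dose entering the depot. Maternal elimination:
  `CL_maternal · induction_scalar / V_maternal` (pregnancy enzyme induction
  and interaction effects are consumed as these two config scalars, not
  modelled mechanistically).
* Placental exchange acts on unbound concentrations: maternal↔placenta via
  `CL_mp = min(CL_int,PD, Q_placenta_maternal)`, placenta↔fetus via
  `CL_uv = min(CL_int,PD, Q_umbilical)` — each exchange capped by its own
  adjacent flow. Apical efflux CL_PM moves drug from placental tissue to
  maternal plasma, acting on the unbound placental concentration
  (placental tissue binding `fu_placenta` defaults to 1, configurable).
  No active maternal→placenta or fetal→placenta terms.
* Fetal elimination defaults to 0 (negligible fetal hepatic clearance).
  The closed-form steady-state K_p,uu for this topology is

  ```
  K_p,uu = [a/(a+e)] · CL_mp / (CL_mp + CL_PM + a·e/(a+e))
  ```

  with `a = CL_uv`, `e = fetal_CL`, reducing to `CL_mp/(CL_mp + CL_PM)` at
  e = 0 — independent of fetal-side flow and of tissue binding. Simulation
  and closed form are cross-checked to 0.5%.
* **Numerics.** The system is linear and time-invariant between dose events,
  so the simulator propagates states with the matrix exponential
  (eigendecomposition when well-conditioned, `scipy.linalg.expm` otherwise)
  instead of a step integrator: mass balance holds to machine precision, and
  the periodic steady state is obtained directly as the fixed point
  `x* = (I − E(τ))⁻¹ E(τ − tlag) u` of the dose-to-dose affine map, which
  makes fitting ~10³ times cheaper than integrating 16 doses per objective
  evaluation. A conventional stiff-ODE route (`method="ivp"`, BDF,
  rtol 10⁻⁹/atol 10⁻¹²) is retained and cross-checked against the exact
  propagator in the test suite.
* Steady state is declared when the final dosing interval's maternal and
  fetal AUCs are within 2% of the previous interval's; `kpuu_from_simulation`
  refuses to report otherwise.
* UV concentration is equated to the fetal central compartment.

The lumped maternal compartment is a deliberate reduction: every quantity
this package computes (K_p,uu, UV/MP shape, AAFE fits, gestational scaling)
depends on the placental-fetal unit and on total maternal exposure, which
enter through `V_maternal`/`CL_maternal`. Published intrinsic efflux
clearances fitted with organ-resolved placental sub-models (tissue binding,
membrane-resolved permeabilities) are **not transferable** to this lumped
topology — the mapping from CL_PM to K_p,uu is model-specific, and only the
K_p,uu scale is comparable across models.

## UV/MP fitting

* The objective is AAFE between observed and simulated UV/MP ratios at each
  dyad's time after dose within the steady-state interval. Fitting the
  ratio (not raw UV) makes the objective invariant to per-dyad maternal
  scale; raw-UV fitting is available behind `fit_on="uv"` for diagnostics.
* Search: bounded scalar minimization over log10(CL_PM), default bracket
  [10⁻¹, 10⁵] l/h, after a 21-point log-grid unimodality/identifiability
  check. Flat objectives set `convergence=False`; ties break toward smaller
  CL_PM (parsimony); a passive-only AAFE at least as good as the fit reports
  "no efflux detectable". A warning flags observation sets collected before
  fetal distribution equilibrium (≲ 3·V_f/(CL_uv·fu_f)).
* `compare_hypotheses` reports AAFE with fitted efflux vs CL_PM = 0 and
  their ratio — the structural analogue of verifying that efflux improves
  UV/MP prediction several-fold for strong substrates.

## Gestational-age scaling

* Passive: `CL_int,PD(GA) = CL_int,PD(term) · SA_ratio`, then capped by the
  GA maternal-placental flow. Efflux:
  `CL_PM(GA) = CL_PM(term) · total_abundance_ratio` (abundance per gram rises
  earlier in gestation but the organ is smaller; the total falls).
* The GA physiology table ships two anchor rows — term (flow 45 l/h, ratios
  1) and GW20 (flow 27.5 l/h, abundance ratio 0.60, SA ratio 0.39 — the SA
  value is *derived* by back-calculation from the published term→GW20
  passive-clearance pair, not printed anywhere) — with linear interpolation
  between them and a hard error outside [20, 40] weeks, where fetal
  physiology is not reliably available. Umbilical flows and fetal volumes in
  the table are plumbing defaults; they do not move steady-state K_p,uu in
  this topology.
* Whether the maternal or umbilical flow is the operative cap at each age is
  not established; each exchange is capped by its own adjacent flow.
* Directional behaviour: for drugs below the flow caps, passive clearance
  falls faster (surface area) than efflux (abundance), so K_p,uu drops at
  earlier GA. For perfusion-limited drugs the *effective* passive drop is
  set by the flow ratio (45→27.5, ×0.61), almost identical to the abundance
  drop (×0.60), and this lumped model predicts nearly unchanged K_p,uu —
  organ-resolved models can differ here, which is part of why fitted
  intrinsic clearances are not transferable.

## Synthetic data generators

**Transwell** (`simulate_transwell`): an event-driven two-chamber simulation
with exact linear-ODE propagation between events (Van Loan block-matrix
integrals for the donor AUC), exact handling of receiver draws
(withdraw aliquot, replace with blank) and donor draws (volume loss
tracked), and multiplicative log-normal measurement noise (default CV 5%,
mean-preserving). Within one run the monolayer is reduced to a *single
effective barrier* with the programmed permeability of that run's
direction — flux = A·P_dir·(C_D − C_R) — so the programmed directional
permeability is identifiable from that run under sink conditions, and the
directional asymmetry (efflux) lives entirely in the difference between the
A→B and B→A coefficients. What this abstraction does **not** represent: the
membrane-resolved coupling by which a strong efflux pump also suppresses
apparent A→B transport through intracellular depletion; recovery tests on
this oracle therefore validate the estimator arithmetic (sampling
corrections, AUC denominators), not monolayer biophysics.

Default conditions mirror the assay protocol: 2 µM donor, 0.5/1.0 ml
chambers, 1.12 cm², receiver samples at 15/30/45/60 min (100 µl), donor
samples at 0 and the end (10 µl). For estimator-consistency studies the
programmed B→A permeability is 3.5·10⁻⁶ cm/s with A→B set by the target
ratio, chosen from the analytic bias bound (bias ≈ AUC_R/AUC_D) so the
receiver stays below ~3% of donor and the sink assumption of the estimator
holds with margin on this schedule.

**Clinical dyads** (`simulate_clinical`): per-dyad log-normal population
variability (default CV 30%) on the maternal parameters
(`V_maternal`, `CL_maternal`, `ka`); one (UV, MP) pair per dyad at a
uniform-random time in [1 h, τ] after a steady-state dose (cord sampling at
delivery is effectively random within the dosing interval); one
multiplicative log-normal residual (default CV 20%) applied to the UV member
so the observed UV/MP *ratio* carries the stated residual CV. The generating
K_p,uu is recorded from the closed form. Maternal *scale* variability
cancels in UV/MP; the residual shape variability from perturbed absorption
does not fully cancel, which is the dominant noise term in recovery studies
that enable population variability.

## Problem sizes in the shipped studies

Simulations use 101 grid points per 12-h interval; fits evaluate a 21-point
log grid plus a bounded scalar search (~35 forward simulations each, ~40 ms
total via the steady-state fixed point). The parameter-recovery study runs
50 seeds × 3 generating K_p,uu values (0.1/0.16/0.5) at 12 dyads and 20%
residual CV; the bootstrap-coverage study runs 20 studies × 15 parametric
refits at the generator's full default noise. Both complete in well under a
minute on one core.

## Known limitations

* The PBPK maternal side is a one-compartment reduction; multi-organ
  maternal distribution, mechanistic enzyme induction/inhibition, and
  drug-drug interaction kinetics are out of scope (consumed as config
  scalars).
* Single-transporter scaling only; no composite P-gp + BCRP efflux.
* Michaelis-Menten saturation is not modelled (single-concentration assay
  protocol); all clearances are linear.
* The Monte-Carlo CI treats ER and abundances as independent; in reality the
  experiment-matched pairing induces correlation that the per-experiment
  point estimates capture but the pooled CI ignores.
* Predictions below gestational week 20 are refused; before ~GW13 the
  maternal-placental circulation is not established and the model concept
  does not apply.
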