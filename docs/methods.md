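# Methods

`trimerqsp` implements a translational quantitative systems pharmacology
(QSP) model for CD3 bispecific T-cell engagers — molecules that bind CD3 on
T cells with one arm and a tumor-surface antigen (here P-cadherin) with the
other, so that the cytotoxic signal is carried by the ternary drug–T-cell–
tumor-cell complex ("trimer"). The package covers the mouse xenograft model
used to quantify the exposure–kill relationship, the derived tumor-static
concentration (TSC) with bootstrap uncertainty, and the human translation
with soluble-target binding.

## Model structure

**Systemic disposition.** The drug follows linear two-compartment kinetics
(central volume `V1`, peripheral `V2`, clearance `CL`, distributional
clearance `CLd`; micro-constants `kel = CL/V1`, `k12 = CLd/V1`,
`k21 = CLd/V2`). In the central compartment the drug additionally binds CD3
on circulating T cells (mass action, `kon_CD3`/`koff_CD3`), and — in the
human model only — the shed soluble antigen (sPcad), a target-mediated sink
whose drug complex is cleared at `kdegcx` (set equal to `kel`). Soluble
antigen is produced at `ksyn = kdeg × baseline`, pinning the pre-dose
homeostasis exactly.

**Tumor exchange.** Drug enters the tumor interstitium through a
Krogh-cylinder exchange rate

    k_up = 2·P·R_cap / R_krogh² + 6·D / R_tumor²,

(permeability `P` = 334 µm/day, diffusivity `D` = 0.022 cm²/day, capillary
radius 8 µm, inter-capillary half-distance 75 µm) with driving gradient
`C1 − C3/ε`, where `ε` = 0.24 is the accessible void fraction. In the mouse
the tumor radius is recomputed from the (dynamic) tumor volume assuming a
sphere at 1 g/mL; the human tumor is fixed at 1 cm radius.

**Trimer formation.** In the tumor the drug binds CD3 (on tumor-infiltrating
T cells) and the membrane antigen (on tumor cells) to form two inactive
dimers and the active trimer. Free receptor pools are expressed per
interstitial volume (totals minus bound species, divided by `ε`) — kept
exactly in that conventional form even though the complexes themselves are not
rescaled; the asymmetry is a bookkeeping convention of this model family and is preserved deliberately.
Only the antigen-bound dimer is internalized (`kint` = 0.1728/day, a 96-h
half-life); the trimer is lost solely by dissociation. Receptor pools are
converted from cell densities with Avogadro's number at the 4-significant-
figure convention (6.023×10²³) used throughout this model family. An
independent algebraic equilibrium solver (`equilibrium_solve`, a bracketed
1-D root find after eliminating one conservation law analytically) serves
as the oracle for the kinetic right-hand side in the test suite.

**Mouse T-cell kinetics.** Administered T cells (5×10⁶/animal ≡ 2.5×10⁹
cells/L in a 2-mL plasma reference volume) leave plasma at `kel_T` =
2.51/day and traffic to the tumor (`k12_T` = 0.002/day, `k21_T` =
0.0005/day). Migrated cells become active after a 5-day lag, expand
exponentially for 7 days at the dose-dependent rate

    P_rate = (0.014/(4 + dose) + 1.5e-5) × dose    [dose in µg/kg, 1/h]

and then contract mono-exponentially at 0.0412/h. The dose entering
`P_rate` is the dose per administration in µg/kg: with mg/kg the implied
7-day expansion at the highest study dose would be < 1.4-fold,
irreconcilable with the observed tumor-infiltrating lymphocyte counts,
while µg/kg gives the observed ~5–40-fold range. One proliferation episode
is anchored to the T-cell inoculation; repeat drug doses do not restart it.

**Tumor growth inhibition.** Unperturbed growth is exponential (`kg0`) with
a sharp switch (`ψ` = 20) to linear growth (`kg`) and a logistic cap
(`M_max`). Trimer drives a saturable kill `k_kill = kmax·T/(kc50 + T)`
acting on the proliferating compartment, whose output passes through three
transit compartments with time constant `τ` before volume is lost. The
tumor-static concentration follows from the stasis balance:

    TSC = kg0 · kc50 / (kmax − kg0).

The 80% confidence interval on TSC is a parametric bootstrap: kg0, kmax and
kc50 are resampled independently from log-normal distributions with median
equal to the point estimate and `sdlog = sqrt(ln(1 + CV²))`; draws with
kmax ≤ kg0 have no finite TSC and are discarded (counted, warned above
10%). Ceff, the combined efficacy threshold across the three xenograft
models, is reported both as the arithmetic and the geometric mean of the
per-model TSCs — conventions differ and the two disagree by ~50% here, so
neither is silently preferred.

## Numerical choices

State integration uses LSODA with rtol 1e-8 and per-state absolute
tolerances (1e-10 nM for concentrations, looser for cell counts and
volumes), restarted at every dose bolus and at the T-cell lag and
proliferation-window boundaries so no discontinuity is stepped over.
Non-negativity is maintained by tight tolerances and checked afterwards,
not by clipping, which would mask stiffness failures. During T-cell
contraction the total tumor CD3 pool can transiently fall below the bound
species; the rate equations as written then produce a negative free-receptor
term that acts as a net dissociation flux, and are integrated as written.

Inside the estimation loops the growth and TGI ordinary differential
equations are integrated with fixed-step classical RK4 (quarter-day step
for the 1-D growth law, eighth-day for the 4-compartment chain, compiled
with numba); both agree with the adaptive reference to better than 2×10⁻⁴
relative, far below the residual noise, at ~10× lower cost.

The bell-shape dose scan reports the *onset of the high-dose decline*: the
highest dose whose steady-state (third-interval) trimer Cmax stays within
0.1% of the scan maximum, refined by log-bisection between grid points.
Under the default human parameters the trimer–dose curve is flat to <1e-5
relative across ~0.2–1.6 mg/kg, so an argmax is solver-noise-dominated and
ill-posed, while the decline threshold (~1.9 mg/kg) is stable; for sharply
peaked profiles the two coincide.

## Estimation (two-stage surrogate)

The reference analysis for such data is population nonlinear mixed-effects
estimation. This package uses a documented two-stage simplification:

1. **Unperturbed growth** is fitted per vehicle animal (weighted least
   squares under the combined additive + proportional error model, residual
   magnitudes re-estimated from pooled residuals and iterated). Each
   animal's initial volume is a free parameter started at its first
   observation: anchoring it at the raw measurement would propagate that
   observation's error through the whole trajectory and bias kg0 upward.
   Population values are geometric medians of the per-animal estimates;
   inter-animal variabilities (omegas) are their log-scale SDs. Animals
   pinned at a search bound (degenerate, e.g. flat trajectories) are
   flagged and excluded from the population summary.
2. **Drug effect** (kmax, kc50, τ, and the residual magnitudes) is
   estimated by pooled maximum likelihood on the treated arms, with growth
   fixed at the stage-1 medians. Each arm's trimer exposure is generated
   once by the mouse model (static-tumor-volume driver mode, so the driver
   does not depend on the parameters being estimated) and interpolated.
   Per-animal baseline volumes and kg0 deviations are profiled on grids
   inside the likelihood, the latter with a log-normal penalty at the
   stage-1 omega (empirical-Bayes shrinkage), so that inter-animal growth
   variability is not absorbed by the kill parameters. Optimization is
   multi-start L-BFGS-B on log-parameters within a biologically plausible
   box (e.g. kmax ≤ 10/day). Censored observations (below the 10 mm³
   caliper floor or an assay limit) contribute one-sided normal
   likelihood terms.

Estimation CV% come from the finite-difference observed-information
matrix; for the drug-effect fit the matrix is regularized by eigenvalue
clipping when ill-conditioned (expected: see below) and the CVs are then
lower bounds. Fit diagnostics cover observed-vs-predicted, weighted
residuals with a runs test, a simulation-based predictive band
(residual + inter-animal resampling), eta-shrinkage, and the parameter
correlation matrix, with the conventional thresholds (|corr| < 0.95,
shrinkage < 40%) flagged.

### Identifiability of the kill parameters

At the fitted parameter values the kill term is effectively a switch:
kc50 = 6.9×10⁻⁵ nM (0.069 pM) while tumor trimer exposure at any feasible
dose (0.01–0.5 mg/kg) peaks at 0.3–23 pM, i.e. 5–300× above it. Simulated
studies at the published design therefore show near-identical complete
responses in every treated arm, and the only kc50 signal — regrowth timing
after trimer decays below kc50 — stays censored under the caliper floor
within the ~65-day study horizon. The profile likelihood is flat in kc50
over more than four decades (downward), and a kmax/kc50 ridge lets kmax
trade against kill duration. Consequently the two-stage surrogate recovers
τ and the growth parameters well, but kmax and especially kc50 are not
individually identifiable from such a study; the parameter-recovery test
documents this rather than hiding it. This is a property of the
study design and parameter regime, not of the estimator.

## Synthetic data

The generators emulate the three observation streams of the xenograft
program: (i) tumor volumes measured twice weekly out to ~63 days, with
log-normal inter-animal variability on kg0/kg (omegas from the fitted
model), log-normal initial volumes (sdlog 0.2 around 150 mm³), combined
additive + proportional noise, a 10 mm³ caliper floor (reported at the
floor, flagged censored) and euthanasia truncation above 3500 mm³;
(ii) destructively sampled serum/tumor drug concentrations with assay
limits of 12.5 and 1.5 ng/mL; (iii) tumor-infiltrating CD3⁺ counts at
pre-dose/24/72/144 h following the proliferation-rate kinetics with
log-normal noise. Each generator draws from its own named substream of the
study seed, so adding one stream never perturbs another. The generators
record the per-animal parameters actually drawn, which is what a
recovery study should target: at n = 10 per arm with omega_kg0 = 0.34 the
realized sample median itself scatters ~11% (1 SD) around the population
value — irreducible by any estimator.

What the generators do not emulate: dropout other than tumor-burden
euthanasia, measurement-schedule irregularities, cage or batch effects,
and any mismatch between the model family and real tumor biology. Passing
recovery tests therefore demonstrate estimator correctness under the
model's own assumptions, not robustness to model misspecification.

## Human translation

Human PK parameters are allometrically scaled from cynomolgus monkey
(exponents 0.9 for clearance, 1 for volumes, −0.25 for first-order
degradation rates; body weights 3.5 and 70 kg). Per-kg quantities pick up
the factor (BW_h/BW_m)^(exponent−1); pure rate constants scale by the
exponent directly. The human model fixes circulating T cells at 5000/µL
and tumor T cells at 6.49×10⁵ cells/g (tumor cells 10⁸ cells/g, the nominal
1:150 effector:target ratio; E:T overrides hold tumor cells fixed), with no
human T-cell proliferation or contraction. Weekly IV dosing is a bolus by
default (drug half-life ≫ any plausible infusion duration); a zero-order
infusion mode is available. No tumor growth/kill dynamics are simulated in
human — the clinical quantity of interest is tumor trimer exposure relative
to Ceff.

## Fixed conventions

- Internal units: hours, nM, mL/kg; per-day inputs converted at the
  container boundary; trimer reported in both nM and pM.
- Mouse body weight 20 g, plasma reference 2 mL, monkey 3.5 kg, human
  70 kg, tumor tissue density 1 g/mL (1 mm³ ≡ 1 mg).
- IV bolus initial condition `C1(0) = dose_nmol_per_kg / V1`, making every
  term of the central-compartment balance nM/h.
- Subcutaneous absorption is not modeled (no absorption stage appears in
  the model equations); the −0.25 absorption exponent is carried in the
  parameter file for completeness only.

## Known limitations

- Well-mixed tumor: no spatial gradients of drug, target or T cells.
- The two-stage estimator is a surrogate for population NLME; omegas enter
  predictive checks, not the drug-effect likelihood.
- kmax/kc50 are structurally non-identifiable at the published exposure
  regime (see above); TSC computed from poorly identified kmax/kc50 should
  be read with the bootstrap interval, not as a point value.
- No cytokine release, toxicity, immune-synapse signaling, or MABEL/dose
  selection logic.
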