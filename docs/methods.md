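# Methods

## Two-site exchange model

Longitudinal magnetization of the *cis* and *trans* conformers during the
ROESY mixing time evolves under d**M**/dt = −A**M** with

    A = [[k_ct + R2c, −k_tc], [−k_ct, k_tc + R2t]],

where k_ct and k_tc (s⁻¹) are the apparent catalyzed exchange rates and
R2c, R2t (s⁻¹) the rotating-frame relaxation rates of the two conformers.
The eigenvalues λ₁ ≥ λ₂ (ordering is a reporting convention only; the
intensity formulas are symmetric under relabeling) give biexponential
closed forms for the two diagonal and two cross-peak intensities, with
I_ct(0) = I_tc(0) = 0. The model is a longitudinal-exchange treatment:
off-resonance spin-lock corrections, transverse coherences and >2-site
exchange are out of scope. The fitted rates are apparent rates at the
enzyme:substrate ratio of the experiment — the model carries no explicit
enzyme concentration.

Derived quantities: k_ex = k_ct + k_tc and, by detailed balance, the
equilibrium trans/cis ratio K_isom = k_ct/k_tc. An independent TOCSY
intensity ratio estimates K_isom without the kinetic fit; the package
reports both and never forces agreement (for the phosphomimetic dataset
the two published-style estimates differ by ~3%, which is why the default
detailed-balance tolerance is 10%).

**Degenerate eigenvalues.** When |λ₁−λ₂| < 1e−8·(λ₁+λ₂+1) the difference
quotient in the closed forms suffers catastrophic cancellation; the code
switches to the analytic limit (t·e^{−λt} terms). Continuity across the
threshold is tested to <1e−8.

**Units.** Rates and relaxation in s⁻¹, times in s internally; files carry
mixing times in ms and are converted only at the I/O boundary.

## ROESY ratio fitting

The fit works in ratio space, r_ct = I_ct/I_cc and r_tc = I_tc/I_tt,
because the initial intensities and the common part of relaxation cancel
there, leaving exactly three identifiable parameters (k_ct, k_tc,
ΔR₂ = R2c − R2t). Internally ΔR₂ is mapped to (R2c, R2t) =
(max(ΔR₂,0), max(−ΔR₂,0)); any common offset is unobservable in ratios.

Both branches are fit jointly (the alternative — per-branch fits — is a
caller choice by constructing single-branch curves) by bound-constrained
least squares (`scipy.optimize.least_squares`, trust-region reflective,
rates ≥ 0). Initialization uses the short-time expansion r_ct ≈ k_ct·t_m
(slope through the origin over the first three nonzero points), ΔR₂ = 0;
five seeded restarts perturb the start log-uniformly in [1/3, 3] and the
best residual sum wins. Standard errors come from the local quadratic
approximation s²(JᵀJ)⁻¹ at the optimum; an indefinite or singular JᵀJ is
reported as "unavailable", never fabricated.

**Weighting.** With no uncertainty information, weights are unit and t_m=0
points (ratio pinned to 0) count like any other, anchoring the build-up.
When the spectral noise floor σ_I is known (always true for synthetic
data; an instrument estimate for real data), `build_ratio_curves`
propagates per-point ratio uncertainties
σ_r = |r|·√((σ_I/I_cross)² + (σ_I/I_diag)²) and the fit weights by 1/σ_r².
This matters: the cis diagonal decays by over an order of magnitude across
the mixing series, so unweighted fits let the noisiest late points
dominate; propagated weights reduce the median k_ex error at 2% intensity
noise from ~25% to ~3%.

**TOCSY constraint.** Optionally k_ct is eliminated via
k_ct = K_isom(TOCSY)·k_tc, enforcing detailed balance against the
independent population measurement; with a consistent ratio this
reproduces the unconstrained optimum (tested).

## CSP titration fitting

Observed composite CSP per peak: √(ΔδH² + (α·ΔδN)²) with α = 0.14, the
standard amide weighting (configurable; the convention is not uniquely
fixed in the field). Binding follows the exact single-site isotherm with
ligand depletion (quadratic solution), valid at titration concentrations
comparable to K_D; the non-depleting hyperbola is its P→0 limit (tested at
P = 10⁻⁶·K_D). Fast exchange is assumed throughout: observed shifts are
population-weighted averages, with no lineshape correction.

Per-peak fits have two parameters (K_D > 0, Δδ_max > 0), initialized at
K_D = ligand concentration at half-maximal CSP and Δδ_max = 1.2× the
maximum observed CSP, with the same multi-start scheme as the exchange
fit. Peaks whose maximal composite CSP is below 0.02 ppm are excluded from
the statistics — non-shifting peaks carry no binding information and only
inflate the aggregate spread. Reporting is the unweighted mean ± sample
s.d. (n−1) over usable peaks, matching the mean-±-s.d. convention for
apparent K_D; a global shared-K_D fit is provided as an option and agrees
with the per-peak mean on clean data.

The reverse-titration design (constant protein, ligand halved each step
plus an apo point) is generated exactly; protein concentration from A280
uses Beer–Lambert with the construct's extinction coefficient.

## Ensemble RMSD

Kabsch superposition by SVD of the covariance matrix, with the determinant
correction that forbids reflections; geometrically degenerate inputs
(<3 atoms, collinear sets) are rejected. Ensemble precision defaults to
"to_mean": all models are superposed onto the coordinate mean, the mean is
refined for two iterations, and the mean model-to-mean RMSD is reported
over backbone N, CA, C (O excluded). The "pairwise" convention (mean over
all pairwise superpositions) is also implemented; to_mean ≤ pairwise holds
on the same ensemble and both are reported by the analysis driver, since
deposited-ensemble precision statements rarely name their convention.
Residue selections accept a numbering offset (±5) because deposited
construct numbering can differ from native sequence numbering; the driver
reports both.

## Synthetic data

Generators are pure functions of (parameters, config, seed) and
byte-reproducible. ROESY noise is additive Gaussian on raw intensities —
not on ratios — because experimental noise lives in the spectrum; ratio
noise then inherits the correct correlation and heteroscedasticity.
Default levels: intensity σ = 1% of the cis initial intensity; shift noise
0.005 ppm (¹H) and 0.02 ppm (¹⁵N), typical HSQC precision. Initial
intensities default to equilibrium populations (I0_t/I0_c = k_ct/k_tc).
The toy structural ensemble is an idealized helical backbone trace with
per-model rigid-body motion plus isotropic jitter of known σ, giving an
analytic expected RMSD of σ·√(3(1−1/M)) for M models.

What the generators do **not** emulate: peak overlap and tracking errors,
baseline/phase artifacts, t₁ noise, intermediate-exchange line broadening,
ROESY offset effects, and real ensembles' spatially correlated
(secondary-structure-dependent) coordinate variance. Passing tests
therefore demonstrate estimator correctness under the stated noise model,
not robustness to spectral pathology.

## Problem sizes and numerical choices

Test-suite simulation studies use 20–50 seeds per condition and the two
experimental mixing-time grids (9 and 8 points); the titration studies use
8 halving steps + apo with 4–10 peaks. Optimizer tolerances are set to
1e−14/1e−15 (xtol/ftol/gtol) so that noiseless round trips are limited by
conditioning, not early stopping; the reported optimum is verified to be
no worse than the generating parameters on noiseless data. Diagonal
intensities below 1e−12 (absolute, or relative to I0 in prediction) are
dropped from ratio construction with a logged warning. All file parsers
reject malformed input with the offending line; nothing is silently
coerced.

## Known limitations

* Standard errors are local (Gauss–Newton) approximations; no profile
  likelihood or bootstrap.
* The exchange fit assumes the two-site model is exact; systematic
  deviations (ROE contributions to cross peaks at short mixing times) are
  not modeled.
* The apparent K_D aggregation treats peaks as independent replicates;
  peaks sharing a binding surface are in reality correlated sensors.
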