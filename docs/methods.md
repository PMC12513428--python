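# Methods

This note records the models the package implements, the numerical and
design choices behind them, what the synthetic-data generators do and do
not emulate, and the known limitations.

## Mass balance

Each living group *i* of a web satisfies, at steady state,

    (P/B)_i · B_i · EE_i − Σ_j B_j · (Q/B)_j · DC_ij − Y_i − E_i − BA_i = 0

with biomass `B` (t/km²), production/biomass `P/B` (1/yr),
consumption/biomass `Q/B` (1/yr), ecotrophic efficiency `EE`
(dimensionless), diet composition `DC_ij` (proportion of prey *i* in the
diet of predator *j*), catch `Y`, net emigration `E`, and biomass
accumulation `BA` (t/km²/yr). The predation term sums over consumers *j*
using the *predator's* `Q/B` — the only reading consistent with the
definition of `DC`; a config switch (`literal_printed_aij`, below) keeps
the alternative dialect for the interaction matrix.

At most one of {B, P/B, Q/B, EE} may be unknown per living group. The
system is then affine in the vector of unknowns (each product term contains
at most one unknown factor), so all coupled unknowns are found in a single
linear least-squares solve over every balance equation that touches an
unknown. Rank deficiency raises an "unsolvable" error naming the groups;
an inconsistent over-determined system likewise; a solved `EE < 0` or
non-finite parameter is "infeasible"; `EE > 1` is recorded as a warning
flag, not an error, so imbalance diagnostics stay inspectable.

Detritus pools are explicit non-living compartments. Each living group
routes its unassimilated consumption `gs·Q` (default `gs = 0.2`, the
conventional unassimilated fraction, overridable per group) and its
non-predation mortality `(1 − EE)·P` to detritus, split equally across
pools; surplus detrital inflow is exported, a deficit is covered by a
flagged import. Diet-column shortfall from 1 is treated as diet import
(feeding outside the system) and never renormalized.

Validation is report-only: `EE ∈ [0, 1]`, gross food-conversion efficiency
`P/Q ∈ [0.05, 0.35]` for consumers (warning outside), diet column sums,
positivity.

## Community matrix and local stability

For each realized link (prey *i*, predator *j*):

    a_ij = −(Q/B)_j · DC_ij / B_i        (top-down, negative)
    a_ji = −e_ij · a_ij,  e_ij = (P/B)_j/(Q/B)_j   (bottom-up, positive)

The matrix covers living groups only (detritus has no `P/B` or `Q/B`), the
diagonal is exactly zero, and mutual predation sums both contributions.
Local stability is `−Re[λ_max(A)]`. Because `trace(A) = 0`, the sum of the
real parts of the eigenvalues is zero, so the measure is never positive —
it is a *relative* local stability, larger (closer to 0) meaning more
stable. `interaction_strength_stats` reports the mean and population
(ddof = 0) standard deviation of `|a_ij|` pooled over both directions of
every link; `scope="predator"` restricts to top-down entries, since the
exact convention in the literature varies.

## Flow network and ecological network indices

Flows are `T[i][j] = B_j (Q/B)_j DC_ij` plus the detrital routing above.
Primary production enters as an import to producers, so every compartment
satisfies inflow = outflow (checked at 1e−6 relative). Consumer
respiration is `(1 − gs)·Q − P`, floored at zero with a warning.

* Trophic levels: `TL = 1` for producers and detritus,
  `TL_j = 1 + Σ_i DC_ij TL_i` solved as a linear system. A diet-import
  shortfall therefore contributes zero trophic mass (import is treated as
  external food below producer level); generated webs have no imports, so
  this convention is inert in the shipped analyses.
* Connectance `CI = L/S²` over living groups (self-links count);
  `L` counts `DC > threshold` (default 0).
* System omnivory index: per consumer
  `OI_j = Σ_i DC_ij (TL_i − (TL_j − 1))²`, averaged over consumers with
  weights `log(Q_j)` for `Q_j > 1` (an unweighted dialect is available).
* Finn's cycling index: with input-normalized
  `G[i][j] = T[i][j]/throughflow_j` and Leontief inverse `L = (I − G)⁻¹`,
  `FCI = Σ_i ((L_ii − 1)/L_ii)·throughflow_i / TST`, where TST is the sum
  of compartment throughflows (inflow convention). The diagonal of the
  input- and output-normalized Leontief inverses coincide, which is what
  the Monte Carlo particle oracle in the tests exploits.
* Predatory cycling index: FCI recomputed after removing detritus
  compartments (their consumption becomes imports, flows into them
  exports). `PCI ≤ FCI` is *not* an invariant — removal changes the
  normalization — and is not asserted.
* Finn's mean path length: `FML = TST / total external input` (primary
  production included in the imports).

The indicator table carries natural-log columns; indices that can be
exactly zero (CI, ISI, SOI, FCI, PCI) use `log(x + 1e−6)`.

## Dynamic simulation

Biomass dynamics follow the standard dynamic extension of the mass-balance
model with foraging-arena consumption:

    dB_j/dt = g_j Σ_i Q_ij − Σ_k Q_jk + I_j − (M0_j + F_j + e_j) B_j
    Q_ij    = a_ij v_ij B_i B_j / (2 v_ij + a_ij B_j)

`g = (P/B)/(Q/B)` is net growth efficiency, `M0 = (P/B)(1 − EE)` the
non-predation natural mortality, `F = Y/B` fishing mortality. Producers
use saturating production `r_i B_i/(1 + h_i B_i)` with `r = 2·(P/B)` and
`h = 1/B0` (maximum production twice the baseline rate). Detritus is a
dynamic donor-controlled pool receiving `gs·Q + M0·B` with a first-order
outflow calibrated at baseline. Vulnerability multipliers `X` are drawn
uniformly on [1, 40] per model and mapped through `v = X·Q0/B0_prey`;
`a = 2 X Q0 / ((X − 1) B0_prey B0_pred)` then reproduces every baseline
flow exactly, making the balanced state an equilibrium of the ODE by
construction (verified to 1e−9 relative at calibration).

**Stability of the baseline.** A press-recovery experiment is only
meaningful if the undisturbed system stays at its baseline. With `X`
anywhere in [1, 40] a substantial fraction of webs has an unstable
equilibrium (positive leading Jacobian eigenvalue): high vulnerability
approaches mass-action dynamics, which random-web theory predicts to be
oscillatory. The calibration therefore redraws the `X` vector (seeded, at
most 20 times) until the equilibrium Jacobian's leading eigenvalue is
below −1e−6/yr, and if no draw qualifies it deterministically contracts
the first draw toward the donor-control limit (`X → 1`), which always
stabilizes. One `X` vector is selected per model and reused across all
scenarios, so the nine-scenario comparison sees identical dynamics.

**Integration.** Classical RK4 on a monthly recording grid whose edges
coincide with the disturbance window. The number of *internal* substeps is
fixed per run from the equilibrium Jacobian's spectral radius
(`n_sub = ceil(step · ρ(J) / 1.0)`); if a pressed trajectory still leaves
the scheme's stability region, the whole run restarts with twice as many
substeps. Both rules depend only on whole-run inputs — there is no
per-step adaptivity — so reruns are bit-identical. Biomasses are floored
at 1e−9 t/km² with a warning.

**Disturbance.** A press multiplies every living group's `M0` by
`(1 + intensity)` over `[t_on, t_off)` and then returns it to baseline;
`press_target="Z"` extends the press to fishing mortality. The scenario
grid crosses intensities {5, 25, 50}% with durations {5, 10, 25} yr; the
(25%, 10 yr) cell is the main scenario. Defaults: one pre-disturbance
year, two post-disturbance years (recovery is sampled one year after
release), monthly step.

## Resistance and resilience

`Y'_n` is the biomass at press onset; `Y_e` the biomass at the largest
|deviation| from `Y'_n` inside the window (`ye_rule="max_deviation"`; the
literal largest biomass is available as `"max_biomass"`, but a press
mortality increase depresses most groups, which would leave resistance
undefined for them); `Y_{e+1}` the biomass one year after release.
Groups with excursion below 1e−6 relative are flagged "unaffected" and
excluded from aggregation; a group back at `Y'_n` to within 1e−6 relative
gets resilience capped at 1e6 and flagged "recovered" (kept in the median,
preserving the higher-is-more-stable ordering while keeping medians
finite). Web-level stability is the median over unflagged living groups;
21-point quantile profiles (0, 5, …, 100%) support the
median-representativeness check.

## Statistics

All variables are natural-log transformed (stability metrics: resistance
and resilience; local stability, being ≤ 0 by construction, stays on its
linear scale) and z-scored before modeling, so reported coefficients are
standardized.

* **VIF screening** from auxiliary least-squares regressions; flag above
  10 (none expected on the synthetic replicas).
* **Mixed models**: random intercept per ecosystem type via REML;
  inference is Wald-z on the fixed effects (at the sample sizes used the
  difference from degree-of-freedom corrections is negligible; the method
  string is recorded in the result object). Degenerate samples fall back
  to OLS with zero random-effect variance, flagged via `converged=False`.
  R²m/R²c follow the variance-partition convention: fixed (resp.
  fixed + random) variance over total.
* **Random forest importance**: permutation %IncMSE — the increase in MSE
  after permuting one predictor, as a percent of the unpermuted in-sample
  MSE; used for ranking, not effect estimation.
* **Piecewise SEM**: each endogenous node is a mixed regression; backward
  elimination removes the single largest-p path per iteration while any
  `p ≥ α` (ties: smaller |coefficient| first). Global fit via Fisher's C
  over Shipley's d-separation basis set (non-adjacent pairs, excluding
  exogenous-exogenous pairs, conditioned on the union of parent sets),
  `C ~ χ²(2k)`. The default starting DAG lets diversity act on stability
  directly and through connectance, interaction-strength heterogeneity,
  and cycling.
* **Mediation**: indirect effect = product of standardized path
  coefficients through one mediator; direct = the retained direct-path
  coefficient (0 if eliminated); total = direct + indirect by
  construction. Percentile bootstrap over webs refits the *final* path
  structure on each resample.
* **Group comparison**: Tukey HSD across ecosystem types with a compact
  letter display (insert-and-absorb).

## Synthetic data

The mechanistic generator emulates curated marine food web collections:
niche-model topology over 6–81 living groups at target connectance
0.1–0.7 (above ≈0.45 niche ranges are drawn free of the predator's own
niche value, since strictly hierarchical feeding caps connectance at 0.5),
one detritus pool, six ecosystem-type labels, four-level taxonomic
resolution indices. Producers get log-normal biomass (log₁₀ mean 1.5,
sd 0.4 t/km²) and `P/B` of 16–160/yr; consumer `Q/B` declines
allometrically with niche position (≈25/yr at the base, ≈2/yr at the top)
with `P/Q` uniform on [0.05, 0.3]. Energetic consistency is built into the
proposal: each consumer's total intake is a drawn fraction of the
production still unclaimed in its prey pool (at most 50–95% of any group's
production is ever exposed to predation, and no take empties a pool), its
diet column records the realized takes, and its biomass follows as
intake/(Q/B) — so a biomass pyramid and skewed interaction strengths
emerge rather than being imposed. Draws are rejection-sampled (≤ 200
attempts, topology refreshed every 25) until all solved `EE ∈ [0, 1]`, the
detritus budget is non-deficient, no biomass falls below 1e−6 t/km², and
validation passes.

What it does not emulate: real collections' taxonomic idiosyncrasies,
multi-stanza age structure, spatially varying fisheries, import-driven
systems, or any fitting of generated indicator distributions to a specific
empirical collection. Passing tests on these webs demonstrates internal
correctness and recoverability of known effects, not agreement with any
particular set of real ecosystems.

The statistical benchmark generator produces linear/path-model data with
known standardized coefficients, an ecosystem-type random intercept of
chosen sd, and residual variance completed toward unit total variance —
the ground truth for the recovery tests (bias, CI coverage, path-set
recovery, mediation).

## Problem sizes used in the shipped analyses

Test-suite and acceptance runs use 200 webs for conservation checks, 40
webs for the century-long equilibrium, monotonicity, and desk-run
analyses, 10–50 replicates at n = 300–500 for statistical recovery, and
1e5 particles for the cycling-index oracle — sizes at which every check's
sampling error is far below its tolerance.

## Known limitations

* Wald-z mixed-model inference is mildly liberal at small group counts
  (6 ecosystem types); backward elimination inherits this.
* The vulnerability-stability conditioning (above) truncates the effective
  X distribution for webs with no stable draw; such webs are flagged.
* `BA ≠ 0` makes the balanced state a non-equilibrium by exactly `BA`
  (biomass accumulation is a deliberate storage term); generated webs set
  `BA = 0`.
* The trophic-level convention for diet imports (TL mass 0) differs from
  tools that assign imports the consumer's own TL; with import-free webs
  this is invisible.
* Quantile partial correlations flag (NaN) any variable numerically
  collinear with its controls rather than reporting noise.
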