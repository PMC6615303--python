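# Methods

## The models

### Light response

Net photosynthesis of a C₃ leaf responds to photon flux density Q as a
non-rectangular hyperbola. The gross term is the smaller root of
κP² − (αQ + P_nmax)P + αQ·P_nmax = 0; net assimilation subtracts dark
respiration R_d. The printed form divides by 2κ and subtracts two
nearly equal numbers at small κ, so the implementation multiplies by
the conjugate:

    gross(Q) = 2αQ·P_nmax / [(αQ + P_nmax) + sqrt((αQ + P_nmax)² − 4καQ·P_nmax)]

This is algebraically identical wherever the literal form is
well-conditioned (verified to 1e-10 relative in tests), continuous in
κ on [0, 1], equal to the rectangular hyperbola αQ·P_nmax/(αQ + P_nmax)
at κ = 0 and to min(αQ, P_nmax) at κ = 1 (the discriminant is a perfect
square there; a `max(disc, 0)` guard absorbs the round-off that would
otherwise produce NaN).

Parameters and units: α (mol CO₂ mol⁻¹ photons) is the maximum apparent
quantum yield — the initial slope; P_nmax (μmol CO₂ m⁻² s⁻¹) the
irradiance-saturated gross rate; κ dimensionless convexity; R_d
(μmol CO₂ m⁻² s⁻¹) respiration, equal to −P_n at Q = 0.

### CO₂ response

P_n(C_i) = εP_nsat·C_i/(εC_i + P_nsat) − R_p: a rectangular hyperbola
in C_i offset by photorespiration R_p. ε (mol m⁻² s⁻¹) is the initial
slope (carboxylation efficiency), P_nsat (μmol CO₂ m⁻² s⁻¹) the
capacity plateau. The CO₂ compensation point follows analytically as
C_i* = R_p·P_nsat/(ε(P_nsat − R_p)), defined only when the plateau
P_nsat − R_p is positive. This is an empirical response model: no
FvCB-style partitioning into Rubisco- and RuBP-limited regions is
attempted, and C_i is used as given (no mesophyll conductance).

### Fitting

Both curves are fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`), tolerances 1e-12 on cost, step and
gradient, at most 500 function evaluations. Starting values are
data-driven and deterministic: the initial slope from an OLS line
through the three lowest (nonzero) setpoints, the respiration offset
from the dark/zero intercept, the plateau from the maximum observed
rate plus the offset, κ₀ = 0.8. Bounds: κ ∈ [0, 1] hard; the remaining
parameters positive with upper limits at 10× the data-implied scale.
Points are treated as i.i.d. regardless of measurement order (the
instrument protocol visits CO₂ setpoints non-monotonically:
400, 250, …, 50, 500, …, 1500). Degenerate inputs — fewer points than
parameters plus one, duplicate-only setpoints, constant response —
raise a `FitError` rather than returning a silent pseudo-fit;
non-convergence is reported through the `converged` flag. Parameter
standard errors come from the Gauss–Newton covariance
(JᵀJ)⁻¹·RSS/(n − p) and are NaN when JᵀJ is singular.

Noise-free synthetic curves at the standard setpoints are recovered to
better than 1e-6 relative error for all three salinity-level parameter
sets; under Gaussian noise of SD 0.3 μmol m⁻² s⁻¹ the mean P_nmax
estimate over 200 replicate fits stays within 2 % of truth (both are
test-enforced).

## Isotope quantities

δ¹³C = (R_sample/R_standard − 1)×1000 against PDB, and
δ¹⁵N = (R_s/R_b − 1)×1000 with R_b = 0.003663 (0.3663 atom % ¹⁵N,
atmospheric N₂); an explicit flag accepts the standard in atom %.
Discrimination Δ¹³C = (δ_a − δ_p)/(1 + δ_p) is only dimensionally
coherent with δ as fractions, so per-mil inputs are divided by 1000,
the expression evaluated, and the result rescaled to ‰ — using a
literal per-mil denominator would shrink typical leaf values about
24-fold, and a test asserts that failure mode. Source air defaults to
δ_a = −8‰ and is overridable. The exact inverse (solving for δ_p) is
exposed and round-trips to 1e-12; it is also how the generator
manufactures δ¹³C from a target discrimination. Total C and N
accumulation is content/100 × leaf dry biomass per plant; aggregation
to treatment level happens after the per-plant product, so summary
accumulations are means of products, not products of marginal means
(the two differ in general).

## Water balance

ET between consecutive irrigations is W_n − W_{n+1} + (AW − D)·ρ with
weights in g, volumes in L and ρ = 1000 g L⁻¹ (setting ρ = 1 lets all
quantities be expressed in g; results are invariant, test-enforced).
Weighing is assumed to happen just before each irrigation event.
Negative ET can arise from weighing noise and is flagged with a
warning, never clipped. The scheduler inverts the leaching relation
AW/ET = 1/(1 − LF); `paper_multiplier` mode applies the one-decimal
rounding of that factor (1.2, 1.4 for LF targets 0.17, 0.29) because
irrigation in practice is dosed from rounded percentages — the
difference between 1.4 and 1/(1 − 0.29) = 1.4085 is one mechanism that
drags the seasonal *actual* LF (ΣD/ΣAW per pot) below its target.
Seasonal reporting rounds LF to two decimals, half-up.

## The synthetic experiment

The generator emulates the study design end to end: 24 pots in four
complete blocks (block labels carry no effect by default; the analysis
layer also omits the block term by default), spot gas exchange at
PPFD 1200 μmol m⁻² s⁻¹ and C_a = 400 μmol mol⁻¹ on days 23, 39, 76
after transplanting, response curves at the ten PPFD / nine CO₂
instrument setpoints, one end-of-season assay row per pot, and a
24-event irrigation ledger per pot.

Default treatment means are the package's calibrated study conditions
for this crop and salinity range (e.g. P_n falling from 21.2 to
13.2 μmol m⁻² s⁻¹ and g_s from 0.81 to 0.32 mol m⁻² s⁻¹ across
0.9 → 7.0 dS m⁻¹; Δ¹³C from 23.61 to 22.17‰). Only factor *marginal*
means are calibrated, so cell means default to an additive
reconstruction: cell(EC, LF) = marginal(EC) + [marginal(LF) − mean over
LF levels]. This preserves the EC marginals and the LF contrasts
exactly; the two published marginal tables are not perfectly mutually
consistent, so both sets cannot be preserved simultaneously, and the
EC direction (which carries the headline contrasts) was chosen. An
`interaction` hook injects per-cell deltas for non-additive scenarios,
since a real LF × EC interaction cannot be reconstructed from marginal
means.

Noise is independent Gaussian per variable, truncated (by resampling,
then clipping) where positivity or range constraints apply (g_s,
biomass, contents, C_i/C_a ∈ [0, 1.2], κ ∈ [0, 1]). Default SDs
(P_n 1.5 μmol m⁻² s⁻¹, g_s 0.06 mol m⁻² s⁻¹, curve points
0.5 μmol m⁻² s⁻¹, Δ¹³C 0.25‰, contents ~1 % DW, biomass ~1 g) were set
once as plausible leaf-to-leaf / pot-to-pot spreads for this species
and instrument class. Spot P_n is tied to g_s through
P_n = pn_cell + b·(ln g_s − ln gs_cell) + ε with b = 8.6 (the
between-salinity-level slope of the calibrated means), so pooled data
reproduce the saturating P_n–g_s shape and a decreasing intrinsic
WUE–g_s relationship. The irrigation ledger is built to be exactly
self-consistent: applied water from the exact scheduler, drainage
LF × AW, and weights propagated through the balance equation (the
default ET trajectory ramps linearly 300 → 1500 g per event with
canopy growth), so recomputing ET returns the input trajectory
identically and seasonal actual LF equals the target.

What the generator does *not* emulate: soil-salinity dynamics and their
feedback on g_s over time, within-canopy leaf heterogeneity,
day-to-day weather forcing of ET, non-Gaussian measurement error, and
any real LF × EC interaction unless injected. Passing tests therefore
demonstrate correctness of the computational chain under the stated
statistical structure, not fidelity to any particular field dataset.

All randomness flows from one master seed through
`numpy.random.SeedSequence.spawn`, one child stream per table, so a
configuration is reproducible bit-for-bit.

## Statistics

The ANOVA layer is balanced-only by design decision: the emulated
experiment is balanced, Type I/II/III sums of squares coincide there,
and silently switching SS types on unbalanced data invites
misinterpretation — unbalanced input raises instead. Model fitting is
delegated to statsmodels OLS; tests cross-check the decomposition
against an independent projection oracle and verify the null Type-I
error rate by simulation. Repeated measurement days are averaged per
pot before testing by default ("average_then_test"), keeping the pot
as the replicate; a pooled mode exists for exploration.

Duncan's multiple range test is implemented from the studentized-range
distribution with Duncan's protection levels α_p = 1 − (1 − α)^(p−1):
the shortest significant range for a span of p ordered means is
q(1 − α_p; p, df_error)·√(MS_error/n). A range is homogeneous if its
extremes differ by no more than its critical range or if it lies inside
an accepted homogeneous range; maximal homogeneous ranges become the
letters, ordered from the largest mean ("a"). Equal group sizes are
required, matching the balanced scope.

The ANCOVA slope test fits P_n ~ group + ln(g_s) + group:ln(g_s) and
reports the extra-sum-of-squares F for the interaction. When both
models fit exactly (zero residual to round-off) the interaction SS is
clamped to zero rather than reporting noise ratios; the common slope is
taken from the additive model, per-group slopes from separate OLS.

Intrinsic WUE is aggregated as the mean of per-observation P_n/g_s
ratios by default. Because P_n/g_s rises as g_s falls, the mean of
ratios exceeds the ratio of treatment means whenever conductance
varies; reports expose both so the aggregation choice is always
visible. Percent contrasts are computed on marginal treatment means and
reported to one decimal.

Significance stars follow the conventional mapping * p<0.05, ** p<0.01,
*** p<0.001, NS otherwise.

## Problem sizes

Test and acceptance runs use the native experiment size (24 pots, 10-
or 9-point curves). Simulation-based checks use 200 replicate fits for
estimator bias, 1000 null datasets for the ANOVA Type-I rate, and
n = 200 per cell for the generator's CLT check — sizes at which the
binomial/CLT tolerances asserted in the tests are comfortably
discriminating.

## Known limitations

- Empirical curve models only; no mechanistic A–C_i partitioning,
  temperature corrections or mesophyll conductance.
- Balanced factorial scope; no mixed models or repeated-measures
  correction across measurement days beyond per-pot averaging.
- The two-way layer tests EC_iw, LF and their interaction; the block
  factor is generated but not modelled by default.
- The Δ¹³C module implements the single-stage discrimination relation,
  not the two-stage diffusion–carboxylation model a + (b − a)·C_i/C_a.
- No multiple-testing correction across response variables.
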