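# Methods

This note records the models, estimators and design choices behind
`bkrect`, in the order the pipeline runs.

## Forward model of BK(mSlo1 ± β2) currents

A BK channel binds 0–4 β2 subunits independently with per-site probability
p, so occupancy is Binomial(4, p).  Each occupancy class n has a two-limb
open-channel I–V: i_n(V) = g·V for V ≤ 0 and i_n(V) = g·V·R_n for V > 0,
with R_n = R_α + n·Δx.  Only the ±100 mV ratio of the I–V is empirically
constrained; the two-limb form is chosen because it makes the ensemble tail
ratio exactly the occupancy-weighted mean of per-channel ratios,
R_α + 4pΔx — the premise of the binomial correction.  The kink at 0 mV is
a modelling artifact and touches no measured quantity (tails are measured
at ±100 mV and the G–V uses rectification-corrected chord conductances).

**Test-pulse families** are generated directly in the additive
double-exponential-plus-pedestal form

    I(t) = A₁·e^(−t/τ_inact) + A₂·e^(−t/τ_act) + C ,

with A₁ = P(1 − q⁴), A₂ = −P, C = P·q⁴, where P is the level's peak scale
(Boltzmann open probability × occupancy-averaged I–V) and q⁴ the binomial
weight of zero-occupancy channels — the only channels that never
inactivate.  This form has I(0) = 0, A = max(|A₁|,|A₂|) = P, and pedestal
fraction C/A = q⁴ exactly, so the pedestal inversion q = (C/A)^¼ is exact
on generator output.  Inactivation is taken complete and its rate
independent of n (one τ_i per variant).

**Tail families** activate fully during a 4 ms +150 mV prepulse, jump
instantaneously to Σₙ wₙ·i_n(V) at repolarization, and deactivate with a
single exponential (time constant = τ_act by default).

**Noise** is additive Gaussian with sd equal to `noise_sd` (default 2 %)
of *each trace's own* peak — per-level gain scaling, so recording
precision is relative.  Scaling noise to the family peak instead would
bury the small-voltage traces (open probability < 0.1) and make the G–V
unmeasurable in principle, which real recordings do not suffer from.
Every noisy simulation requires an explicit seed; identical seeds give
bit-identical patches.

**Preset catalog.**  Channel variants are named presets holding
(R_α, R_eq_full, p, τ_act, τ_inact, V50, κ, g, noise): the α-only control,
the wild type (p = 0.93), the eight single Cys→Ser mutants, the four
measured double mutants and the twelve charge probes.  Defaults: τ_act =
2 ms, τ_inact = 20 ms (25 ms for conserved-cysteine mutants), V50 =
−15 mV, κ = −12 mV, 20 kHz sampling, 200 ms test pulses, 20 ms tails.
R_α is reported variously as 1.12, 1.15 and 1.2 in the source material;
the catalog uses 1.12 throughout and the value is configurable.

## Trace fitting

`fit_biexponential` is nonlinear least squares with time constants on a
log scale (positivity structural, bounded to [1 µs, 100 s]).
Initialization: C from the mean of the final 10 % of the window, τ_act
from the 1−1/e rise time, τ_inact from a log-linear regression of the
late decay.  Eight τ multi-start perturbations (×3/÷3) run before a fit
is declared non-convergent; convergence and degeneracy (constant traces)
are flagged, never silently fabricated.  Components are labelled by the
convention τ₁ ≥ τ₂, which makes (A, C) invariant to component exchange.
The default fit window starts 0.5 ms after step onset; fits are
referenced to trace time so amplitudes are onset amplitudes regardless of
window.

"Instantaneous" tail amplitude is not uniquely defined by a sampled
decay; the default estimator fits each tail with a single exponential and
back-extrapolates to the repolarization onset (settling-window
independent, sampling-rate invariant to < 0.5 %).  A windowed mean over
0.15–0.35 ms after onset is the fallback (near-zero tails) and an
alternative method for sensitivity checks; the method used is recorded.

The Boltzmann G–V is fitted exactly as printed,
G/G_max = (1 + exp((V − V50)/κ))⁻¹, with κ free-signed: the printed form
decreases with V for κ > 0, so the usual increasing G–V simply fits with
κ < 0.  G–V points from a test-pulse family are chord conductances with
the outward limb divided by the patch's measured rectification ratio, so
both limbs share one conductance scale; levels whose excursion is below
6× the trace's noise floor are skipped.

## Occupancy correction

From a patch's tail I–V and test-pulse fit: R = |I₊₁₀₀/I₋₁₀₀| (exact grid
points, no interpolation), q = (C/A)^¼, then

    Δx = (R − R_α)/(4p),   R_eq = R_α + (R − R_α)/p,   p = 1 − q.

Numerical guards: a negative fitted pedestal clamps q to 0
(`clamped-pedestal` flag); p below 0.05 refuses the correction
(`LowOccupancyError`) because the 1/p divisor amplifies noise beyond
usefulness; q within 0.05 of 1 is the α-only phenotype — the result is
returned uncorrected with the `alpha-only` flag and q = NaN.  R_α is a
per-analysis configuration constant (default 1.12), not re-estimated per
patch.

**Pedestal pooling.**  The pedestal fraction is the precision bottleneck:
for one 200 ms trace at 2 % noise the best achievable σ(C/A) is ≈ 3·10⁻⁴,
and the fourth root turns that floor into per-patch q scatter of ±0.06.
Since q⁴ is level-independent, `analyze_patch` averages the signed C/A
ratios over all saturated outward steps of the family (V ≥ +60 mV, well
above V50) before taking the fourth root; time constants and quality
flags still come from the +100 mV reference fit.  A consequence worth
stating plainly: when the true pedestal is far below the noise floor
(wild-type-like q = 0.07 gives q⁴ ≈ 2.4·10⁻⁵), no estimator can resolve
it from a noisy trace, and the clamped fourth-root estimate sits at a
noise-floor plateau near 0.05–0.1.  Quantities defined on noise-free
traces (the wild-type q check) are therefore evaluated noise-free.

Aggregation reports mean ± sd (n) per cohort (sem available as an
option); α-only patches contribute R_eq but not q.

## Pairing decision engine

Evidence is consumed as cohort summaries (mean ± sd, n) because that is
the granularity at which mutant panels are reported.  The one-way ANOVA
is computed directly from summary statistics,

    F = [Σ nᵢ(x̄ᵢ − x̄)² / (k−1)] / [Σ (nᵢ−1)sᵢ² / (N−k)] ,

with the p-value from the F(k−1, N−k) upper tail; it is algebraically
identical to a raw-data ANOVA on any samples realizing the stated
moments, which the test suite verifies against an independent raw-data
oracle.  Zero within-group variance with unequal means yields p = 0,
flagged.  The Welch test for charge probes uses the same summary route.

The procedure: (1) split the eight single mutants at the largest gap in
their q means (higher-q cluster = conserved subgroup — cysteines whose
loss destabilizes α/β2 association); (2) enumerate all perfect matchings
within each subgroup (≤ 3 each, so enumeration is exact); (3) score each
matching by its number of similar triplet verdicts at α = 0.05 (no
multiple-testing correction by default, matching the similarity
criterion as practiced; a Bonferroni option exists); ties break on the
number of consistent two-site charge probes whose label pair appears in
the matching, then lexicographically; (4) report the best matching's
pairs whose triplets pass; all other labels are unpaired.  A missing
double mutant makes a triplet *untestable* — a distinct verdict that
never counts for or against a matching.  Measured cross-subgroup doubles
are evaluated and logged as diagnostics but never enter matching
enumeration.  C2/C4 are reported unpaired purely because their triplet is
untestable/failed; the glycosylation-related interpretation of that
ambiguity is outside this engine's scope.

The synthetic panel generator (`simulate_evidence_panel`) assigns each
true bond one R_eq perturbation δ ∈ −[0.20, 0.36] (any mutant disrupting
that bond shifts by δ; doubles across two bonds accumulate both), bond-
level q values of ≈0.42/0.58 (conserved) and ≈0.08/0.10 (non-conserved),
cohort sd ≈ 0.05 and n = 6–8.  By default the reported means equal the
topology-implied truth (panels emulate transcribed cohort tables); with
`sample_means=True` the means additionally carry sd/√n sampling noise.
In that regime each true triplet independently fails its α = 0.05 test
5 % of the time by construction, so exact recovery of all four pairs is
capped near 0.95⁴ ≈ 81 % — the robust statistic is the selected matching,
which equals the generating topology in ≥ 95 % of panels.

## Digestion band prediction

A construct is the base sequence with the TEV recognition site (ENLYFQG)
inserted after residue 137 and the HA tag (YPYDVPDYA) appended; all
cysteine bookkeeping stays in base numbering with an explicit coordinate
map.  TEV cuts between Q and G (the standard ENLYFQ/G convention — the G
stays on the C-terminal product; the convention is an assumption, stated
here).  Fragments and intact disulfides (not reduced, neither half-
cystine mutated) form a graph whose connected components are the
covalent species on a non-reducing gel.  The HA band is *released* when
the HA-bearing component is the lone C-terminal fragment — equivalent to
no intact disulfide spanning the cut, an equivalence the suite verifies
by brute force over all 105 perfect matchings of eight cysteines × 9
mutant states.  Digestion cannot distinguish re-pairings confined to one
side of the cut (e.g. C1–C2 vs C1–C5); it cleanly separates same-side
from cross-cut pairings, which is exactly the information it contributes
on top of the electrophysiology.

Masses are SDS-PAGE-style apparent masses: average amino-acid masses plus
one water per chain (via biopython), plus a glycan mass of 3000 Da per
occupied N-X-S/T sequon (X ≠ P, auto-detected within the loop region,
default residues 46–185).  The glycan value is a calibration chosen so
the full glycosylated construct lands near the observed ~34 kDa band; it
is not a claim about glycan composition, and mass comparisons are made at
±15 % accordingly.

**Sequence fixture.**  The packaged β2 FASTA is a *synthetic* stand-in
(so labelled in the filename and header): a 235-residue sequence encoding
every functionally constrained landmark — the eight cysteines at their
canonical positions as the only cysteines, Q83, the N88/N96 glycosylation
sequons, S100, D104, L114, K137, K141/S143, K147, S173/Y175 — with filler
chosen so the construct masses match the observed bands (C-terminal TEV
fragment 13.07 kDa, full glycosylated construct 35.6 kDa).  Every
digestion conclusion depends only on these landmarks, not on the filler.
The module accepts any user FASTA for other subunits.

## What the synthetic data do and do not show

The generator reproduces the macroscopic observables the inference
consumes: binomial occupancy mixing, exact per-class rectification,
pedestal-coded unbinding, Boltzmann activation, and seeded relative-
amplitude noise.  It omits single-channel stochastic gating, capacitive
and series-resistance artifacts, leak, drift, and any occupancy
dependence of inactivation rate.  Passing tests therefore demonstrate
that the estimators invert this forward model correctly and are robust at
the stated noise level — not that the model captures every feature of
real recordings.  Two further caveats: the measured wild-type ensemble
ratio under the binomial model is R_α + 4pΔx ≈ 1.80 at p = 0.93, slightly
below the full-occupancy 1.85 (cohort tables that print both identically
implicitly assume p = 1); and applying the R_eq correction to cohort
*means* does not reproduce per-patch-corrected cohort averages (e.g. C1S:
1.31 from means vs 1.38 per patch) — the pipeline corrects per patch.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script
each run in well under a minute on one core: cohorts of 5–12 patches,
200 ms test pulses and 20 ms tails at 20 kHz, 200 synthetic panels for
the recovery property, and the exhaustive 105-matching digestion check.
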