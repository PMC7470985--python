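# Methods

This note documents the models implemented in `overflux`, the defaults and
why they were chosen, the synthetic-data generator's scope, and the
numerical decisions a user should know before trusting a number.

## Scope and data model

The pipeline begins at *quantified* endpoint concentrations of secreted
metabolites in spent culture medium. NMR (or LC) spectral processing,
peak assignment and quantification are upstream of this package and out of
scope. The canonical unit is mM; micromolar values are converted once, at
the table boundary (`<name>_uM` columns). Replicates are stored flat —
the study design of 5 biological × 5 technical replicates is kept as
metadata only, because only pooled means ± SD are modelled; no nested
variance components are estimated. A metabolite absent from one treatment
is "not measured" and is excluded from downstream maps, never imputed as
zero.

The default registry holds the eleven secreted metabolites detected in the
study system — acetate (C2), succinate (C4), formate (C1), propionate
(C3), lactate (C3), histidine (C6), cysteine (C3), cystine (C6, one
disulfide molecule, not 2 × C3), glutathione (C10), asparagine (C4),
alanine (C3) — with fixed standard carbon counts and one precursor-node
assignment each.

## Secretion flux maps

`carbon_flux` normalizes carbon, not molarity: F(x) = 100·c_x·C_x / Σ cᵢ·Cᵢ.
Its denominator is *secreted* carbon only, so the shares always sum to
100 % and no CO₂ term can appear. The CO₂ share comes from the separate
glucose balance (`infer_co2`): CO₂ carbon = 6·glucose − secreted carbon −
biomass carbon, reported on the input-carbon scale (basis
`glucose_balance`). Both bases are labelled on the result because they are
not interchangeable. Biomass carbon uses 0.5 g C per g dry weight and the
OD-to-biomass factor 0.54 g·OD⁻¹·L⁻¹ (both configurable). A negative CO₂
remainder within 10 % of input carbon is clamped to zero and flagged
(measurement noise); beyond 10 % it raises as a mass-balance violation.

Network exports (DOT/GraphML) are deterministic: nodes and edges are
emitted in sorted order, shading is flux/max-flux in [0, 1], and
change-versus-control colours are green (increase), red (decrease), gray
(no change).

## Feedback inhibition

The additive null model for the supplemented species includes the
supplement (x_null = x_init + A_sup); all other metabolites keep their
control level. The fold variance is implemented as

x_var = x_obs / x_null − 1,

the fold deviation from the null: 0 means no effect, negative values mean
"missing" metabolite, −1 is complete suppression. (The source literature
prints this formula in a typographically garbled form; the ratio form is
the interpretation that reproduces its worked numbers and sign language.)
The suppression coefficient is the unweighted OLS slope of x_var against
supplement concentration, computed on per-treatment means including the
(0, 0) control point, with the squared Pearson correlation reported. A
perfectly flat response reports R² = 1 (the correlation is degenerate
there; the slope 0 carries the information).

Significance tests are pooled-variance Student's t by default (Welch
selectable), with no multiple-testing correction — matching the original
analysis; a Benjamini–Hochberg view can be layered on by the user. Exact
published coefficient tables are *not* reproduction targets: the
concentrations behind them are plotted, not printed, so the package's
guarantee is parameter recovery on synthetic data instead (below).

## Response scenarios

Endpoint responses are modelled as Δx(A) = a·A + b·A², with a the direct
(enzyme-level) per-mM coefficient and b the regulatory one; within a time
course the accumulation follows a normalized ramp g(t), giving
Δx(t, A) = a·A·g(t) + b·A²·g(t)². The quadratic basis for b is a design
choice: a purely linear regulatory term would be unidentifiable from
endpoint data, and discriminating "feedback only" from "synergistic
feedback with regulation" requires a second identifiable basis. The
balanced scenario is generated directly from its defining constraint —
endpoint Δx = −x_init at every nonzero supplement level (curves overlap) —
because no fixed (a, b) pair can satisfy it across levels.

Classification fits the nested pair Δ = a·A versus Δ = a·A + b·A² through
the origin and keeps b only if (i) an F test retains it at α = 0.05 and
(ii) the regulatory term is practically identifiable: |b|·A_max² must reach
25 % of |a|·A_max. The second condition is a parsimony threshold:
multiplicative noise alone induces a small same-sign curvature (|b̂| an
order of magnitude below real regulatory effects) that passes the F test a
few percent of the time; requiring a non-negligible effect share removes
those false positives without touching genuine b ≠ 0 data. Mixed-sign
significant fits have no scenario in the taxonomy and fall back to the
b = 0 family by the sign of a. Balanced is detected first, from its
overlap signature (means within 3 SE + 5 % of −x_init, no trend in A),
and all-zero data is reported as additive with a = 0 and a null-effect
flag. Per-scenario residual sums of squares of sign-constrained fits are
reported as diagnostics; the decision rule is the documented test, not a
raw argmin, which would always prefer the two-parameter family.

## Growth curves

Doubling time is ln 2 / slope of the OLS fit of ln(OD) on time. The
exponential window, when not given, is chosen as the maximal contiguous
run of ≥ 3 points with log-linear R² ≥ 0.99 and positive slope (ties →
higher R², then earlier start). This selection rule is the package's own;
with a stationary plateau present it can admit one near-plateau point and
bias Td by a few percent, so precision work should pass an explicit
window. On noise-free exponentials the estimate is exact to machine
precision. Dose-response fits are degree-1 or degree-2 polynomials
(parabolic needs ≥ 4 distinct doses so a residual degree of freedom
remains); the growth t test accepts either raw replicates or summary
statistics (mean, SD, n), since published growth tables come as summaries.

## The curated FBA model

The shipped stoichiometric model is a deliberately small central-carbon
network of an anaerobic glucose fermenter (~50 reactions): lumped EMP
glycolysis to PEP, pyruvate kinase and pyruvate phosphate dikinase,
pyruvate dehydrogenase and pyruvate:ferredoxin oxidoreductase, pyruvate
formate-lyase, the Ack/Pta and acetyl-CoA-synthetase acetate routes, LDH,
the reductive branch (malate dehydrogenase, fumarase, fumarate reductase)
to succinate, the methylmalonyl route to propionate, a lumped oxidative
branch to 2-oxoglutarate/succinyl-CoA, nitrogen assimilation (GDH, GS),
both asparagine-synthesis routes (asparagine synthetase and aspartate
ammonium ligase), aspartate oxidase feeding an NAD-cofactor precursor,
serine/cysteine synthesis, formate–THF ligase, ferredoxin hydrogenase as
the redox valve, and a lumped biomass reaction. It is **not** a
genome-scale reconstruction and makes no quantitative biomass claims; the
published genome-scale predictions are treated as qualitative behaviours,
of which the testable ones on this network are: biomass invariance across
the four high-glucose media, interchangeability of the two asparagine
routes, steady state at every optimum, and objective monotonicity under
bound relaxation.

Two toy simplifications are intentional and load-bearing:

* **Moiety-level formulas.** Carriers (CoA, THF) and currency couples
  (ATP/ADP/AMP, NAD(H), ferredoxin) carry empty C/N formulas; acyl-CoAs
  count only their acyl carbons. Elemental validation therefore checks
  carbon skeletons, which is what secretion accounting needs.
* **Route-degeneracy by construction.** Glutamine synthetase is lumped
  energy-neutral, so asparagine synthetase (glutamine-dependent) and
  aspartate ammonium ligase have identical net stoichiometry and cost.
  This realizes the observed interchangeability of the two routes exactly
  — deleting either leaves the objective and every exchange flux unchanged
  to solver precision — which a strict ATP accounting could not do while
  biomass is ATP-limited. Acetyl-CoA synthetase is irreversible toward
  acetyl-CoA: with an untracked pyrophosphate, a reversible ACS plus
  Ack/Pta and adenylate kinase forms a perpetual ATP cycle; acetate
  *production* proceeds through Ack/Pta, the energy-conserving route.

Biomass demands 30 ATP per unit, which makes growth ATP-limited at both
glucose levels: excess glucose carbon overflows as secreted acetate
(generating that ATP), and supplemented acetate or formate — which yield
no net ATP on this network (acetate activation costs what succinate
formation returns; formate has no dehydrogenase) — cannot change the
optimum. That is the mechanism behind the high-glucose invariance.

The LP is solved with HiGHS (scipy.optimize.linprog) at tightened
feasibility tolerances (1e-10), then a second LP fixes the objective and
minimizes Σ|v| (flux variables plus absolute-value majorants). Without
this lexicographic stage, alternate optima make per-reaction comparisons
between media meaningless; with it, repeated runs are bit-identical.
Exchange fluxes follow the convention positive = secretion, negative =
uptake; a medium is a map of maximum uptakes that sets exchange lower
bounds, with the grid using glucose 2.78 (high) / 0.1 (low) and
supplement 10 mmol·gCDW⁻¹·h⁻¹, over a base medium of ammonia and CO₂.
Flux changes between conditions are labelled increased / decreased /
zero-net / direction-change / no-change at a 1e-6 tolerance.

## Synthetic data generator

The generator is the package's stand-in for the wet-lab study design and
defines the conditions under which the statistical guarantees are stated:
acetate at {0, 0.5, 1, 5, 10} mM, 25 replicates per treatment, optional
10 mM formate and 10 + 10 combination treatments, multiplicative Gaussian
noise at cv 0.08 (anchored to the printed control acetate 6.6 ± 0.5 mM;
printed SDs scale roughly with means, which is why the noise is
multiplicative; a constant-SD variant can be had by scaling inputs).
Baselines are anchored to printed concentrations where available
(acetate 6.6 mM; lactate 120, histidine 101, cysteine 242, cystine 209,
glutathione 121 µM); succinate (3.0), formate (1.5), propionate (0.8),
alanine (0.150) and asparagine (0.080 mM) are placeholders consistent
with the reported abundance ranking, not published values.

Per-metabolite feedback uses the feedback-only endpoint form: the mean at
level A is x_null(A)·(1 + s·A) with s the fold-variance slope. Because
concentrations are non-negative, x_var ≥ −1, so a generating slope must
satisfy |s| ≤ 1/A_max = 0.1; published-style coefficient magnitudes up to
≈ 1 per mM are therefore *not representable* as data-generating slopes.
The defaults keep the reported suppression *hierarchy* (acetate weakest →
alanine strongest) and space the magnitudes evenly across the feasible
range (−0.001, −0.01, −0.02, …, −0.10): evenly spaced true values are what
makes a rank-recovery guarantee meaningful, since the slope-difference
standard error at this design is ≈ 0.004 per mM and near-tied true slopes
would make ranking information-theoretically unrecoverable. Negative
draws are clamped at zero and counted; at the defaults, clamping affects
< 1 % of draws. Growth curves are exponential with the true doubling time
following a parabola in dose anchored at the printed 1.322 h control, an
optional stationary cap, and multiplicative OD noise.

What passing tests on this generator do **not** show: robustness to
heteroscedasticity beyond the cv model, biological-versus-technical
variance structure (a single pooled cv is used), correlated metabolite
noise, non-exponential growth phases (lag, death), or measurement
artefacts of spectral deconvolution.

## Statistical guarantees (as tested)

At the study design with cv 0.1: suppression-slope bias < 5 % of the true
slope for |s| ≥ 0.05 and full rank recovery in ≥ 95 % of 200 runs;
scenario classification ≥ 95 % correct per scenario over 200 simulations
(observed: 100 %), with pure-feedback data reported as feedback inhibition
without regulation. Flux maps sum to 100 within 1e-9 and match a direct
hand computation to 1e-12; FBA optima satisfy S·v = 0 within 1e-9; the
t statistic matches the closed form to 1e-10; pipeline bundles are
byte-identical under a fixed seed (outputs carry no timestamps; the
manifest stores the configuration, seed and per-file SHA-256).

## Pipeline and determinism

All randomness descends from one top-level seed, fanned out with fixed
per-stage offsets. The acceptance script reduces its seed modulo 2²⁰
before deriving per-run seeds so all derived seeds stay far below 2³¹.
Profile tables are written with shortest round-trip float representation
and read back with correctly rounded parsing, so write → load is
bit-exact.

## Known limitations

* The CO₂ share from `infer_co2` depends on the basis chosen (secreted
  versus input carbon) and on the biomass carbon assumptions; the result
  object records both so the choice is never silent.
* The suppression regression uses per-treatment means; per-replicate
  regression gives the same point estimate at a balanced design but a
  different (smaller-looking) standard error, which is why no slope CI is
  reported.
* The curated FBA network cannot secrete amino acids and does not model
  regulation, so it reproduces directional/invariance behaviour only.
* The auto-selected exponential window can bias doubling times by a few
  percent when a stationary plateau is present (see above).
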