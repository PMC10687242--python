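# Methods

## Scope and data model

The pipeline operates on three tables: an ASV count table (samples × ASVs,
integer reads, with per-ASV taxonomy strings), a sample frame describing
the 3 × 3 factorial design (microcosm, replicate 1–5, day ∈ {0, 1, 3, 7},
treatment ∈ {none, phage, antibiotic}, invader level ∈ {no, low, high}),
and a density series (total cells/mL per microcosm per day, optionally a
living fraction). Counts are read and written as TSV (ASVs as rows, first
column `asv_id`, optional trailing `taxonomy` column) and as BIOM v2.1
HDF5; the BIOM writer/reader is a minimal in-package implementation of the
2.1 layout (ids, CSR/CSC matrices, a taxonomy metadata dataset) built on
h5py.

Similarity — not dissimilarity — is the module currency throughout, and
conversion to distances happens only inside PCoA and PERMANOVA.

## The simulator

`simdata` generates experiments with the statistical structure the
analysis assumes. Within a microcosm the state is (N_i, P, R, A): per-taxon
cell densities (taxon 0 = invader), phage (PFU/mL), a dissolved-organic-
matter pool R in cell-equivalents/mL, and antibiotic activity A. One Euler
step of length dt applies, in order:

1. **Monod growth** `dN_i = µ_i R/(K_i+R) N_i dt` with yield 1 (growth
   consumes R one-for-one), total consumption capped at the pool;
2. **antibiotic kill** `−k A N_i dt` for susceptible taxa (susceptibility
   follows the taxon's class label), with optional exponential decay of A;
3. **phage infection** of the invader: `lysed = a P N_0 dt`, burst-size
   phages released per lysed cell, first-order phage decay;
4. **background death** at a per-taxon rate;
5. **DOM release**: killed, lysed and dead cells return to R at
   `dom_yield` (< 1, so recycling is dissipative);
6. **demographic drift**: each N_i is replaced by
   `Poisson(N_i·V)/V` at effective volume `drift_volume`
   (V → ∞ recovers the deterministic ODE — a tested limit).

Fluxes are capped at their source pools so no state goes negative.
Integration uses fixed-step forward Euler, dt = 0.05 day by default,
validated against the closed-form exponential at saturating resource
(≈ 0.2% error at dt = 0.002; the Euler bias is ~µ²dt/2 per unit time).

The experiment layout mirrors the factorial design: one seeded resident
community (lognormal rank-abundance), three source bottles at the
configured invader doses, a split into treatments × replicates, phage or
antibiotic applied at the first step boundary after one hour, daily 11%
medium exchange, counts emitted on the sampling days (negative-binomial
read depth, multinomial reads, so rarefaction depths are meaningful) and
density emitted daily with lognormal readout noise. Microcosms that go
fully extinct yield no amplicon sample (density 0 is still recorded). A
deterministic twin of every group plus the drawn per-taxon parameters are
returned as ground truth for parameter-recovery tests.

### Community structure and the feast–famine regime

A strictly mass-balanced single-pool model with homogeneous consumers
cannot produce a mid-experiment density surge: the community eats the DOM
pulse as fast as it is released. The default taxon set therefore encodes
the ecology that makes the observed regime possible:

* **bulk oligotrophs** (most taxa): µ ≈ 0.9/day, very high half-saturation
  (K = 5×10⁶), slow turnover (death 0.12/day) — they barely respond to a
  DOM pulse;
* **opportunist r-strategists** (*Pseudomonas*- and *Aquirufa*-type
  classes): 3× growth boost, low K (2×10⁵), 4× turnover, rare at t = 0
  (inoculum share down-weighted ×0.02), antibiotic-resistant;
* **the invader**: no net growth (full fitness penalty), 5× mortality —
  an unsuccessful invader that decays over days and fuels the DOM pool.

With a high invader dose this yields the characteristic trajectory: early
decline while the invader dies, a surge after day 2 as opportunists bloom
on the lysate (peak near day 5), and a famine decline to day 7 as the
pulse is spent and bloomers crash. The same structure makes antibiotic
treatment produce a resistant-opportunist bloom and a large richness loss.

Defaults encode the study conditions: resident density 6.25×10⁵ cells/mL,
invader additions 0 / 1.38×10⁵ / 1.07×10⁶ cells/mL, phage doses 3.12×10⁵
(low-invader) and 3.12×10⁶ PFU/mL (high-invader *and* uninvaded phage
groups), dilution fraction 0.11/day, 5 replicates, days 0–7. The dose and
baseline-density values are kept as independent configuration: the
percentage increases they imply (≈22% and ≈171%) are printed elsewhere as
24% and 190%, and the simulator does not attempt to reconcile the two.
The inoculum of each microcosm is Poisson-sampled at an effective
bottleneck volume `init_volume` = 5×10⁻⁴ mL — replicate communities start
slightly different, as real transfers do — and ongoing drift uses
`drift_volume` = 1 mL. Under these defaults the simulated experiment also
reproduces the qualitative assembly pattern of interest: similarity rates
decrease with invader amount in untreated and phage-treated groups, and
the antibiotic drives strong replicate divergence.

### What the generator does not emulate

No read-level sequencing artefacts (chimeras, PCR bias, copy-number
variation), no phage co-evolution or resistance emergence, no spatial
structure, no live/dead compartment chemistry, and a single substitutable
resource rather than a realistic DOM spectrum. Passing tests therefore
demonstrate that the *statistical machinery* behaves correctly on data
with the assumed generating structure — not that real communities follow
this model.

## Diversity and ordination

Hill numbers are computed on each sample's count vector; q = 0 counts taxa
present, q = 1 uses the Shannon limit, general q ≥ 0 uses
`(Σ p_i^q)^{1/(1−q)}`. Evenness defaults to the Hill ratio `D_1/D_0`
(Pielou's J is available); a single-taxon sample is defined perfectly
even. Bray–Curtis and Sørensen similarities are validated against
scipy's `braycurtis` and `dice` distances.

Averaged similarity matrices follow the rarefy-and-average recipe: for
each of `repetitions` draws, every sample is rarefied to a fixed depth by
multivariate-hypergeometric sampling (without replacement; samples below
the depth are excluded and listed), the metric matrix computed, and the
element-wise mean returned with the depth and repetition count recorded.
When both metrics are requested they share the same rarefaction draws —
halving the subsampling cost without biasing the means. The default depth
of 26,448 reads matches the normalisation used in the motivating study;
synthetic read depths (mean 5×10⁴, NB dispersion 25) make that depth
feasible for nearly all samples.

PCoA applies Gower double-centering to `−d²/2` with `d = 1 − S` and an
eigendecomposition. Axes with negative eigenvalues (Bray–Curtis is
semi-metric) are reported but excluded from both the returned coordinates
and the explained-variance denominator; no Lingoes/Cailliez correction is
applied. Coordinates are re-centered explicitly to remove numerical
drift. Equivalence with scikit-bio's implementation (up to axis sign) is
tested.

## PERMANOVA

One-way partitioning of squared distances (total minus within-group sums,
pseudo-F with (a−1, n−a) degrees of freedom), p-value
`(1 + #{F* ≥ F}) / (1 + n_permutations)` under free permutation of group
labels. Permutations can by chance reproduce the observed partition, and
those ties count as exceedances, so the attainable minimum p on a 5+5
design is ≈ 2/C(10,5) ≈ 0.8% per draw — not 1/(n_perm+1); the type-I
error simulations confirm the test holds its nominal level. The
mean-of-repetitions variant reruns the test on each independently rarefied
table and averages F, R² and p. The among-group sum of squares can be
slightly negative for semi-metric distances under worse-than-chance
groupings; R² is clamped at 0 in that case (pseudo-F is reported as-is).
The pairwise treatment-vs-control tests the pipeline runs operate within
one day × invader-level stratum, so free permutation (no strata
restriction) is appropriate.

## Differential abundance

Testing operates on absolute abundances. ASVs first pass a prevalence ≥ 5%
AND total abundance ≥ 2500 copies/mL filter (inclusive thresholds,
documented and tested at the boundary). The built-in method tests the
difference in group means of log₁₀(abundance + 1) by free label
permutation — all ASVs share each permutation, preserving between-ASV
correlation — with Benjamini–Hochberg adjustment across retained ASVs. A
pseudocount of 1 copy/mL guards ratios and logs against zeros. External
tools (corncob, DESeq2, ANCOM-BC run elsewhere) contribute per-ASV
significance flags through the same interface; the consensus rule keeps
ASVs flagged by all supplied methods (configurable), and an ASV is
*reported* only if, additionally, its treatment/control mean-abundance
ratio is below 0.2 or above 5. No further correction is applied after the
consensus step — requiring unanimity is the conservative step.

## Trend models and marginal-mean ratios

Density (log₁₀-transformed) and richness follow polynomial mixed models —
cubic and quadratic day terms respectively, fully crossed with treatment
and invader level, with a random intercept per microcosm (the repeatedly
sampled unit; a day-within-microcosm random effect is a documented
alternative reading of "sampling day per unit" but the microcosm-level
intercept is the default). Singular or non-converged mixed fits fall back
to OLS with cluster-robust standard errors and are flagged in the result.

Estimated marginal means are evaluated from the fixed-effect design at
each observed day × invader level (no extrapolation outside the fitted
day range); treatment/control ratios are back-transformed from log₁₀ for
density (delta-method SE `ratio·ln10·SE_diff`) or formed directly with a
delta-method gradient for richness. Within each day × invader-level
family the two treatment-vs-control comparisons receive a Dunnett-style
adjustment: `p_adj = P(max_j |Z_j| ≥ |z|)` under the joint normal of the
contrast estimates (bivariate rectangle probability by inclusion–
exclusion), with a Holm bound as fallback for degenerate contrast
covariance. On balanced noiseless data the back-transformed ratios equal
direct geometric-mean ratios (tested to 1e-9).

## Replicate similarity rate and assembly calls

For each experimental group and sampling day, all C(r, 2) unordered pairs
of replicate microcosms contribute their similarity; the pair keeps a
stable identity across days and acts as the repeated-measures unit. The
default estimator fits one linear mixed model — similarity against
day × treatment × invader level with a random intercept per pair — and
extracts each group's marginal day slope with a delta-method SE (factors
with a single observed level are collapsed to keep the design full rank);
a per-group estimator fits independent random-intercept regressions. Day
enters linearly: the statistic is a *rate*, in similarity units per day.

The assembly call sharpens the sign interpretation with uncertainty:
selection iff the 95% CI lies above zero, drift iff below, indeterminate
otherwise — so noise is never labelled as signal. Pairs sharing a
microcosm are not modelled as cross-correlated (a known limitation of the
pair-level random intercept).

### Benchmark regimes

Two single-group generator configurations provide ground truth:

* **Selection regime** — replicates receive a finite Poisson-sampled
  inoculum (`init_volume` = 2×10⁻⁴ mL) so they start measurably
  different; drift is off; one resident grows much faster than the
  uniform field (µ = 4.0 vs 1.0/day, fixed via `mumax_values` so no draw
  produces near-tied winners), resource is saturating, turnover high.
  Every replicate sweeps to the same dominant taxon, similarity rises,
  and the slope is positive. Literally identical replicates would give a
  flat series whose estimated slope sign is a coin flip — initial
  variability is what lets selection *visibly* converge replicates; and a
  far smaller inoculum would instead leave the winner absent from some
  replicates, with selection amplifying the difference.
* **Drift regime** — identical inocula, equal growth rates (no
  selection), small `drift_volume` = 2×10⁻³ mL: replicates diverge by
  neutral demographic noise and the slope is negative.

Across 20-seed batches the pipeline calls ≥ 90% of selection-regime runs
non-drift with slope ≥ 0 and ≥ 90% of drift-regime runs non-selection
with slope ≤ 0 (observed: 100% for both across several seed streams).

## Problem sizes and numerical choices

The shipped analyses use the full 45-microcosm design with 30 resident
taxa; benchmark regimes use 8–15 taxa, 5 replicates, rarefaction depth
5000 with 10 repetitions, and 999 (tests) or 199 (large null batteries)
permutations — sizes chosen so the complete validation battery, including
200-run type-I simulations and 20-seed recovery batches, runs in minutes
on one core. Ties in permutation statistics are counted conservatively
(≥ with a 1e-12 slack). Seeds propagate through `numpy` `SeedSequence`
spawning, so results are reproducible and independent of execution order.

## Known limitations

* The generator's ecology is deliberately minimal; its parameters were
  chosen to realise the qualitative regimes described above, not fitted
  to data.
* The CI-based assembly call inherits the mixed model's normal
  approximation; with only four sampling days the CI can be optimistic
  when the pair-level variance is near zero (the OLS fallback uses
  cluster-robust SEs for this reason).
* The built-in DA method is a two-group location test on log absolute
  abundance; it does not model overdispersion or compositional bias the
  way the external engines do — it stands beside them, not in for them.
* BIOM support covers the v2.1 core needed for interchange of counts and
  taxonomy, not group metadata or arbitrary observation metadata.
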