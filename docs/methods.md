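# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. It states nothing that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

A sample is one RNA-seq (or physiology) measurement of a clone isolated at
a *flask* — the unit of evolutionary time within one strain's ALE
trajectory (flask 0 is the preculture). Each strain contributes an ordered
chain of assayed flasks labelled WT (first), intermediate, and EP (last).
A *jump* is the difference between two consecutive assayed flasks of one
strain: in growth rate, in omics profiles, and in the set of mutations
gained. Differencing a design with F assayed flasks over S strains yields
F − S jumps (22 flasks over 6 strains → 16 jumps).

All tables are comma-separated UTF-8 with header rows; identifiers are
opaque case-sensitive strings; empty cells are missing values and are
never silently imputed — every consumer either skips the record with a
warning or raises.

## Convergence/divergence testing

Per phenotype, per-strain WT and EP means are reduced to vectors of all
unordered pairwise absolute differences. The test statistic is
U = #{(EP distance < WT distance)} + ½·#ties; convergence is the upper
tail, divergence the lower. p-values use the normal approximation with
continuity correction (±½) and the standard tie correction on σ². The
continuity correction is on by default because it is the convention that
reproduces the reference value checked in the test suite
(U = 19, n = (15, 15), lower tail → p = 5.7 × 10⁻⁵; without the
correction, 5.3 × 10⁻⁵). BH-FDR is applied within each direction across
the phenotype panel; a phenotype is labelled by whichever one-sided
direction passes, and both cannot pass simultaneously.

Distances are raw (unstandardised): each phenotype is tested separately,
and the rank statistic is invariant to affine rescaling of that
phenotype's values (a property test asserts this).

**Known limitation — anti-conservative null.** The s(s−1)/2 distances are
mutually dependent functions of only s values, while the Mann-Whitney
variance formula assumes two independent samples. Monte-Carlo measurement
(the red calibration test in `tests/test_acceptance.py`) shows a raw
rejection rate of ≈ 14% per direction at α = 0.05 for a neutral phenotype
with 6 strains, not 5%. Consequently the FDR of the labelled sets is
somewhat above nominal; the recovery of genuinely convergent/divergent
phenotypes is unaffected (≥ 90% of planted labels are recovered at the 5%
FDR setting across seeds). The test is implemented exactly as defined; a
calibrated alternative would require a permutation null over strain
means, which is out of scope here.

The exact-enumeration oracle for the normal approximation covers balanced
sample sizes n = 3..8, where the approximation is within 0.02 absolute of
the exact tail everywhere. At n = 2 the discrete exact distribution (only
6 arrangements) deviates by up to 0.044; n = 2 distance vectors arise only
from two-strain comparisons, which the distance transform is not meant
for (a single pair of distances carries no rank information).

## Activity projection and explained variance

Projection solves A = M⁺·X in the Moore-Penrose sense over the exact
string intersection of gene ids, refusing to run if fewer than 50%
(configurable) of the basis genes match or if the restricted basis loses
column rank. No centering is applied by default — the projection is the
literal inverse-model equation — but a per-gene centering against a named
reference sample set is available; all downstream contrasts (differences,
correlations, ANOVA) are invariant to that choice.

Explained variance on a sample subset is 1 − ‖C(X − M·A)‖²_F / ‖C(X)‖²_F
with C the per-gene centering operator over the subset (centered mode,
default) or the identity (uncentered mode). Centering both the residual
and the denominator makes the quantity a true fraction of per-gene
expression variance and gives EV = 1 exactly when X = M·A.

## DIMA: differential iModulon activation

The null is a log-normal fitted by closed-form maximum likelihood
(μ = mean log d, σ = sd log d) to the pooled absolute activity differences
between biological replicates, across all iModulons. Pooling keeps the fit
sample large (a per-iModulon option exists); absolute differences are used
because signed differences include negatives on which a log-normal is
undefined. Zero differences are dropped with a logged count; a fit on
fewer than 10 differences warns.

A change Δ = mean(condition 2) − mean(condition 1) gets
p = P(LogNormal(μ, σ) > |Δ|), BH-adjusted across iModulons, and is
significant only if additionally |Δ| > 5 activity units (the
minimum-change rule; an optional fold-change filter `min_fc` exists but is
off by default — the absolute threshold is the primary rule, and both are
exposed because the two conventions appear in differential-activity
practice). DIMA is antisymmetric in condition order and its empirical
type-I error under the generator's null is ≤ α + 2 Monte-Carlo standard
errors (asserted at 100 seeds), with ≥ 95% power for a planted shift of
10 against the 5-unit threshold.

## Trade-off detection

PCA runs on the jump-differenced activity matrix with columns
mean-centered and no variance scaling (activities share a scale;
rescaling would distort loadings). Outlier handling mirrors a
manual-curation workflow: an explicit (jump, iModulon) exclusion list
whose cells are replaced by the column mean of the remaining jumps —
removing their influence while keeping the jump — plus an optional
automated rule flagging |robust z| > 4 (1.4826·MAD), off by default.

Candidates are iModulons with |loading| > 0.10 in any component explaining
≥ 5% of variance. Pair testing uses flask-level (replicate-averaged)
activities, not jump differences: trade-off lines are relations between
activity levels, and differencing would discard the strain-intercept
structure the ANCOVA models. The ANCOVA is the common-slope model
y ~ x + strain with R² from that fit; the interaction F-test
(strain-specific slopes) is reported alongside as `homogeneity_p` rather
than folded into R², since the common-slope fit is the quantity
thresholded. The default R² threshold is 0.95 (configurable via
`--r2-min`; 0.90 is a defensible looser setting and the discrepancy
between the two conventions is noted in the output metadata). Pair
orientation is canonicalised alphabetically so results are independent of
candidate order.

Note that any positively and any negatively growth-coupled iModulon form
a genuinely anti-correlated pair through their shared growth dependence;
the synthetic-truth object therefore exposes `implied_negative_pairs()`
(planted pairs ∪ growth-implied pairs) and the recovery suite counts
false positives against that set.

## Mutation correlates

Features are binary gains per jump, aggregated at gene level by default
(all nucleotide events in a locus collapse to one column) or kept at
nucleotide level. Features present in fewer than two jumps are untestable
and dropped with a logged count. Events observed at unassayed flasks are
attributed to the first assayed flask at or after the observation, with a
warning. The association statistic is point-biserial correlation with its
two-sided t p-value — the smallest-assumption binary-vs-continuous test at
n ≈ 16 jumps — with a seeded label-permutation alternative that agrees
with the t-based p within 0.02 at these sizes (asserted by an
exact-enumeration test at 8 jumps). BH runs separately within flux targets
and iModulon targets. Strain-specific refinements ("locus(strain)"
features) are generated only for loci mutated in ≥ 2 strains.

## Growth and trajectory utilities

Growth rate is the OLS slope of ln(OD600) on time. The smoothed fitness
trajectory applies isotonic regression (pool-adjacent-violators) to the
per-flask rates and interpolates the adjusted nodes with a PCHIP cubic,
which preserves monotonicity and never overshoots between nodes; the
sampled grid always includes the node positions. Doubling time is
60·ln 2 / rate minutes. Replicates are collapsed by arithmetic mean per
flask before jump differencing. OD600 converts to dry weight at
0.32 gDW/L per OD unit.

Replicate QC removes discordant biological replicates by pairwise R² of
log-TPM (< 0.9 flags a pair): in groups of two both members are removed
(no arbiter exists); in larger groups the member with the lowest mean
pairwise R² is removed iteratively until all remaining pairs pass.
Whether R² is computed on all genes or a filtered core set is the
caller's choice of input matrix; the pipeline uses the matrix as loaded.
Gene-level QC keeps genes ≥ 100 nt with ≥ 10 fragments per million mapped
reads in every sample, FPM computed per sample over the fragments present
in the table (self-contained definition; no external library-size
bookkeeping).

## Synthetic-data generator

The generator emulates a six-strain ALE campaign: 6 strains × 3–4 assayed
flasks (22 total, 16 jumps) × 2 biological replicates; growth rates rise
monotonically from strain-specific wild-type values (0.55–0.90 h⁻¹) to
plateaus drawn from [0.98, 1.11] h⁻¹. All randomness derives from a
single integer seed; regeneration is byte-identical.

Planted signals and their scales (defaults):

| Signal | Default | Why |
| --- | --- | --- |
| Growth-coupled iModulons | 3 positive + 3 negative, 40 activity units per 1/h around a 0.85 h⁻¹ pivot | six growth-correlated iModulons is the structural template; the slope makes per-strain \|R\| ≈ 1 at the planted noise |
| Trade-off pairs | 3 pairs, coupling c ∈ {1.0, 0.8, 1.2}, driver sd 5, coupling noise sd 0.3 | negative coupling with near-perfect ANCOVA R² (> 0.95 in ≥ 90% of seeds, asserted) |
| WT offsets | 4 iModulons, +15 units in one strain each, WT flask only | large relative to replicate noise so the ANOVA screen recovers exactly these when no other strain structure exists |
| Causal mutations | 4 flux-targeting + 8 activity-targeting loci, effect ±10; each gained in 2–3 jumps | mirrors the 4-flux + 8-iModulon correlate structure; two carriers minimum keeps the feature testable |
| Replicate noise | symmetric ±d/2 per replicate pair with \|d\| ~ LogNormal(0, 0.5), plus N(0, 0.3) per-sample measurement noise | matches the assumed form of the DIMA null so type-I calibration is checkable; the measurement term keeps between-flask deltas non-degenerate |
| Activity scale | meaningful shift = 10 units vs the DIMA threshold of 5 | the threshold is absolute, so the generator must fix a scale |
| Phenotypes | 62 total: 10 convergent (86% of them additionally growth-coupled, β = ±15), 2 divergent, 50 neutral; WT dispersion sd 3, EP sd 0.15, neutral sd 1 | convergence = wide WT spread collapsing to a tight EP cluster; the growth-coupled fraction mirrors the observation that most convergent phenotypes track growth |
| Expression | X = M·A + N(0, 0.1), 1000 genes × 24 iModulons, column sparsity 0.10, unit-norm near-orthogonal columns | full column rank (redrawn and logged otherwise); a constant per-iModulon activity level (sd 15) supplies the between-gene dynamic range that real log-TPM has, so replicate R² sits near 0.99 without touching any contrast |

Non-negativity of expression is achieved by one global additive shift (the
most negative entry), recorded in the dataset object; clipping is only a
guard against round-off. The shift adds a single constant per iModulon to
projected activities, identical across samples, so differences,
correlations, ANOVA contrasts and trade-off fits are unaffected — tests
assert exact recovery modulo that constant.

**What the generator does not emulate:** read-level noise, gene-length or
GC bias, realistic regulatory network topology (iModulon supports are
random), isotopomer measurement structure behind the flux CIs, allele
frequencies within populations, and non-monotone fitness trajectories.
Passing recovery suites therefore demonstrates that the statistical
machinery recovers the signal classes it targets at realistic effect
sizes and sample sizes — not that it would recover them under every noise
structure of real data.

Problem sizes used in the default test and acceptance runs (6 strains, 22
flasks, 24 iModulons, 300–1000 genes, 10–100 Monte-Carlo seeds per suite)
were chosen as the smallest sizes at which every planted signal class is
exercised with stable recovery statistics.

## Pipeline

Stages execute in the workflow order simulate/load → replicate QC →
projection → convergence and growth screens → replicate-null fitting and
DIMA → WT-discriminating and growth-correlated screens → jump differencing
→ PCA/ANCOVA trade-offs → mutation correlates → report. Every stage logs
input shapes, dropped-record counts, thresholds and the seed; a stage
failure aborts with the stage name and leaves a `FAILED` marker beside any
partial outputs. The summary report (JSON + text) contains only counts
that are recomputable from the stage CSVs (asserted by a recount test),
and reruns with a fixed seed are byte-identical. Threshold defaults:
convergence/growth/trade-off/mutation FDR 0.05, WT-discrimination FDR
0.005, DIMA minimum change 5 and α 0.05, growth screen median |R| > 0.75
and median p < 0.05, PCA weight 0.10 and EV 5%, ANCOVA R² 0.95, replicate
R² 0.9.
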