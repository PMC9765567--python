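# aleomics

Analysis toolkit for **multi-strain adaptive laboratory evolution (ALE)
multi-omics**: given flask-resolved measurements of several bacterial
strains evolving toward maximal growth rate — gene expression
(log2(TPM+1)), iModulon gene weights, physiological/fluxomic phenotype
panels, flux estimates with 95% CIs, and mutation tables — it answers the
questions a comparative-ALE study asks:

- **Which phenotypes converge or diverge across strains** between the
  wild-type (WT) and evolved-endpoint (EP) flasks?
- **How does transcriptome composition shift**, expressed in a few dozen
  iModulon activities instead of thousands of genes?
- **Which iModulons track growth rate in every strain**, and which pairs
  trade off against each other (one up, one down)?
- **Which selected mutations correlate with jump-specific changes** in
  reaction flux or regulatory activity?

It ships a synthetic-data generator that emulates a six-strain, 22-flask,
duplicate-replicate ALE experiment with planted, recoverable signals for
every stage, so the whole pipeline is testable end to end.

## The statistics at the core

**Convergence/divergence.** For each phenotype, the per-strain means at WT
and EP are transformed into vectors of all pairwise distances
(s strains → s(s−1)/2 distances; 6 strains → 15). A one-sided
Mann-Whitney U test, U = #{(EP dist < WT dist)} + ½·ties, with normal
approximation

> z = (U ± ½ − n₁n₂/2) / σ,  σ² = n₁n₂(n₁+n₂+1)/12 − tie correction,

asks whether EP distances are stochastically smaller (convergent, upper
tail of U) or larger (divergent, lower tail). Benjamini-Hochberg FDR is
applied per direction across the panel.

**iModulon activities.** Expression decomposes as X = M·A with M a fixed
ICA-derived gene-weight basis; new samples are projected by the
least-squares solution A = M⁺·X over the shared gene set.

**Differential iModulon activation (DIMA).** A log-normal null is fitted
to absolute activity differences between biological replicates; a change
Δ between two conditions is significant if its BH-adjusted upper-tail
probability passes α **and** |Δ| > 5 activity units.

**Trade-offs.** PCA of jump-specific activity differences (ΔA between
consecutive assayed flasks) selects candidate iModulons (|loading| > 0.10
in components with ≥ 5% explained variance); candidate pairs with negative
flask-level Pearson correlation, BH-significant common slope, and ANCOVA
R² > 0.95 (strain-specific intercepts) are called trade-off pairs.

**Mutation correlates.** Mutations gained in each jump form binary
features over jumps; point-biserial correlation (or a seeded permutation
test) screens them against jump-specific Δflux and Δactivity, BH-corrected
within each target family.

## Worked example

```bash
aleomics run --seed 1 --out-dir out/
```

simulates the default six-strain dataset (44 samples = 22 flasks × 2
replicates), runs every stage, and writes per-stage CSVs plus
`report.json`/`report.txt`. The seed-1 report contains, among others:

```
n_flasks: 22
n_jumps: 16
n_convergent: 13
n_divergent: 5
n_growth_correlated_imodulons: 6
n_tradeoff_pairs: 13
n_mutation_correlates_flux: 4
n_mutation_correlates_imodulon: 10
explained_variance: 0.980862
```

Reading: differencing 22 flasks over 6 strains gives 16 jumps. All six
planted growth-coupled iModulons are found with their correct signs (IM01–
IM03 positive, IM04–IM06 negative). The 13 trade-off pairs comprise the 3
explicitly planted negative couplings plus the 9 pairs implied by opposite-
sign growth coupling (a positively and a negatively growth-coupled
iModulon are necessarily anti-correlated), plus one marginal call within
the 5% FDR allowance. All 4 flux-targeting causal loci are recovered; the
13 labelled convergent phenotypes include 9 of the 10 planted ones (the
distance-transform test is anti-conservative under the null — see
`docs/methods.md` — so a few neutral phenotypes are also flagged).

The same stages are available as library calls (`aleomics.
classify_convergence`, `project_activities`, `dima`, `detect_tradeoffs`,
`screen_correlates`, ...) and as individual subcommands (`simulate`,
`project`, `converge`, `dima`, `tradeoffs`, `mutcorr`, `report`).

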