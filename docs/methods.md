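# Methods

This note documents the models, estimators, and numerical choices behind
`introgh2`, and what the synthetic test bed does and does not establish.

## Synthetic world

### Haplotype panel

`simulate_panel` draws a phased 0/1 matrix of `n_haplotypes × n_variants`.
Variants are split into `n_blocks` independent LD blocks, one chromosome
label per block, positions 1-based at fixed `bp_spacing` (default 500 bp).
Within a block a latent Gaussian field with correlation
`exp(-within_block_decay · distance)` is binarized at frequency-matched
*rank* thresholds: the `round(p·n)` haplotypes with the smallest latent
values carry the alternate allele. Consequences:

* the alternate-allele count of every column is exact (frequency
  conservation holds bitwise, and no column is monomorphic);
* pairwise r² decays with distance inside blocks and is ~0 across blocks;
* target alternate frequencies are Uniform(0.01, 0.5), giving a flat MAF
  spectrum with both rare and common variants.

Defaults (1006 haplotypes, decay 1e-4/bp) emulate a European-scale
reference panel with strong local LD; neighbor r² ≈ 0.9 at 500 bp, decaying
to ~0.1 over 12 kb. This is stronger than typical array data and is the
stress case for the estimators, not a claim of realism.

**Planted introgression.** Each `SegmentSpec(length_bp, n_archaic,
frequency)` claims one block. Exactly `round(frequency · n_haplotypes)`
carrier haplotypes are chosen (an error if that rounds to 0 or all); the
segment's archaic columns are overwritten so carriers hold all archaic
alleles. Archaic columns are therefore in perfect mutual LD but, being
overwritten, independent of the surrounding latent field — LD expansion of
an archaic allele finds the other archaic alleles of its segment and
(essentially) nothing else. The planted intervals are recorded 0-based
half-open, and `write_sprime_like` emits per-population segment tables
(chrom, start, end, population, n_comparable, match_rate) and per-variant
tables (CHROM POS ID REF ALT SEGMENT ALLELE SCORE ALTAIMATCH VINDIJAMATCH)
with deterministic match-status assignment, so files round-trip bitwise.

### Trait model

All effects are on the **standardized-genotype scale** (per-allele effects
divided by `√(2p(1−p))`); the per-variant heritability contribution is
`β_j²` and marginal effects are correlations. The source literature is
silent on the scale its tools assume; fixing the standardized scale makes
`Σβ² = h²` exact and is the convention of LD-score methods.

Given an annotation membership table,

* `β_j ~ Normal(μ_j, (h²/M)·w_j)` where the multipliers `w_j` equal the
  target fold-enrichment of the variant's annotation (product over
  memberships if annotations overlap — enrichment targets are exact only
  for disjoint annotations) and background variants absorb the remainder so
  the expected total is exactly `h²`; jointly infeasible targets (implied
  background variance < 0) raise.
* `μ_j` is the configured directional mean on the archaic-oriented allele,
  applied to archaic-flagged members only (orientation is undefined
  elsewhere) and sign-converted to the alternate allele.
* `α = Rβ` block-wise with `R` the panel-estimated correlation matrix;
  `α̂ = α + ε`, `ε ~ N(0, R/N)` block-wise (eigenvalue-clipped square
  root, since the sample `R` can be rank deficient); `Z = √N · α̂`.

`TraitTruth` records `β`, `α`, `realized_h² = Σβ²` and exclusive
per-annotation shares `Σ_{j∈c} β_j² / Σβ²`.

A caveat worth knowing: a directional mean on archaic alleles in perfect
mutual LD adds `(Rμ)_j²` to the expected χ², which exceeds the
variance-model term `Σ R²μ²` by roughly the segment's archaic count. Traits
with strong planted directionality therefore show *larger* apparent
heritability enrichment than the variance target alone — a real property of
directional architectures, and the reason enrichment calibration tests use
directionality-free traits.

## Stratified LD-score regression

`compute_ld_scores` computes `ℓ(j,c) = Σ_{k∈c, |pos_k−pos_j|≤window} r̃²`,
per chromosome, self term included. With `adjust=True` (default),
`r̃² = r² − (1−r²)/(n−2)`, the standard finite-panel bias adjustment. When
the GWAS is *generated from the panel's own R* (as in this package's
simulations) the unadjusted score is the model-consistent choice, so the
calibration tests and the acceptance runs pass `adjust=False`.

`fit_sldsc` regresses `Z²` on `{N·ℓ(j,c)}` with a free intercept
(`intercept=1.0` can be fixed; on exact identity-LD data it must be, since
the LD-score column is then constant and collinear with a free intercept).
Two weighting schemes:

* `"block-gls"` (default): per LD block, generalized least squares with
  `Cov(Z_j², Z_k²) = 2·E[Z_j²]·E[Z_k²]·r²_jk` — the actual covariance of
  correlated χ² statistics under the Gaussian model, computable here
  because the panel's block structure is known. Fitted means come from a
  step-1 overcounting-weighted fit, clamped at the polygenic floor of 1 so
  weights stay bounded. At desk scale (M = 5000, strong LD) this halves the
  per-replicate enrichment SD relative to diagonal weights and removes the
  occasional weight blow-ups that made the diagonal scheme heavy-tailed.
* `"diagonal"`: the classical contract — overcounting weight
  `1/max(ℓ_total, 1)` times heteroskedasticity weight `1/fitted²`, iterated
  once; tested against an independently coded statsmodels WLS.

Reporting restricts to common variants (panel MAF > 0.05, configurable):
`h²_(c) = Σ_{j∈c∩common} σ²_j` with `σ²_j = Σ_c τ_c a_cj`, and
`Enrichment_c = (h²_(c)/h²)/(|c∩common|/M_common)`. The identity
`enrichment · prop_snp = prop_h2` holds exactly, and an all-ones annotation
has enrichment exactly 1 (per-column sums reuse the accumulation order of
the total).

**Uncertainty.** Delete-one-block jackknife over 200 contiguous equal-sized
units by default (the remainder spreads over leading blocks). Under
block-GLS the units are contiguous groups of whole LD blocks,
`g = min(200, #blocks)`, so each delete-one refit remains a valid GLS.
Enrichment p-values use a normal approximation on the jackknife SE.
Negative `h²_(c)` estimates are not truncated.

**Trait QC and aggregation.** `trait_qc` gates on effective N > 40,000,
heritability SE < 6× the expected SE for the sample size (the expected SE
is caller-supplied metadata — the source pipelines do not publish the
formula), sex imbalance < 3:1, no nonlinear ordinal coding, and
heritability z > 7. `aggregate_group` summarizes per-trait enrichments per
domain/chapter/subchapter: two-tailed one-sample t vs 1, optional
two-sample t between named groups, one-tailed binomial on the count of
traits below 1, and Benjamini–Hochberg FDR at 0.05 across groups
(zero-variance groups report an undefined t and are excluded from the FDR).

## Directionality

`orient_to_archaic` flips each GWAS Z to the archaic(-linked) allele of its
LD-expanded proxy (e.g. Z = +6 with effect allele A but archaic allele C
becomes −6); rows where neither GWAS allele matches are dropped and
counted, duplicates keep the highest-r² source. `threshold_and_prune`
keeps `p < p_cut` and then greedily scans by ascending p, keeping a variant
iff its r² to every kept variant is strictly below the prune threshold (at
prune r² = 1 only perfect proxies collapse). `direction_test` compares the
counts against 50/50: `χ² = Σ (obs−E)²/E`; the one-tailed p is the
majority-direction tail, computed as `Φ(−|n₊−n₋|/√n)` (identically half
the upper χ²₁ tail). The 15-vs-2 configuration gives χ² = 9.941 and
p = 8.1e-4.

### SLDP regression

With `Cov(α̂) ∝ R`, the GLS estimator of `E(α̂|ν) = r_f √(h²_g) Rν`
jointly with the signed background columns `B` reduces to
`θ = (AᵀRA)⁻¹ Aᵀα̂` for `A = [ν̃, B]` — no inverse of `R` is needed, and a
rank-deficient panel `R` is harmless. `ν` is normalized to unit length
internally; `r_f = θ_ν/√(h²_g)`, reported in percent. Negating `ν` negates
`r_f` exactly. `h²_g` is an input (the pipeline feeds the S-LDSC estimate).

The signed background is five equal-count MAF bins of ±1 minor-allele
indicators (+1 when the alternate allele is minor; ties at 0.5 count as
minor); projecting them out absorbs genome-wide minor-allele directionality
from negative selection or stratification.

**Empirical null.** The published recipe flips the signs of ν in "large
blocks". Two desk-scale corrections were needed for a calibrated null:
(1) flip units must be contiguous groups of *whole LD blocks* — units that
cut LD blocks miss cross-unit covariance and are anti-conservative; (2)
with the background conditioned on, flipping ν alone does not carry the
background's coupling to the data. The implementation flips the
marginal-effect vector block-wise instead — the operational dual of
flipping ν (only block inner products enter the statistic) and an exact
randomization test under per-block symmetry of α̂. Because the design
cross-products stay fixed, each draw is a linear functional of the signs
and 10,000 draws cost milliseconds. The default 300 blocks truncate to the
number of LD blocks; p is two-sided on |r_f| with the +1 correction.

Residual tables (α̂ and Rν after projecting out the background only) are
stored oriented to the Neanderthal-linked allele, matching the plotting
convention of the field, so window correlations are comparable with
published per-window r values.

## Window scan and overlap null

`scan_windows` centers a 30-kb window (0-based half-open
`[pos−1−15000, pos−1+15000)`) on every regression variant and keeps it if
it holds ≥ 15 variants and the Pearson correlation between residual α̂ and
residual Rν satisfies r² > 0.5 (either sign). Overlapping candidates merge
(abutting windows stay separate) and r is recomputed over the merged span
without re-filtering. Merged windows survive iff they contain a variant
with marginal GWAS p strictly below 1e-4 and at least one archaic-matching
allele.

The overlap test's universe is the same construction without the trait
filter (and without the r² filter, following the stated null construction);
hits need not match universe spans bitwise — each must lie inside it. The
null resamples |hits| windows from the universe without replacement; since
overlap is a binary mark per window, the null count is drawn exactly as a
hypergeometric, which is both faster and identical in distribution to
explicit resampling. `p = (1 + #{null ≥ observed})/(n_shuffles + 1)`, so p
is never 0 and attains `1/(n_shuffles+1)` in the extreme configuration.
The overlap statistic is discrete: p-values are exactly uniform only on
attainable tail values and conservative between them, so uniformity checks
need large universes/hit sets.

## What a green test establishes — and what it does not

The synthetic world has exact block LD, no recombination-map structure, no
demography, no genotyping error, no allele-frequency differentiation
between "discovery" populations, and archaic alleles decoupled from the
surrounding latent LD. Green calibration tests therefore establish the
estimators' statistical correctness under their own model assumptions —
unbiasedness, jackknife coverage, null uniformity, sign recovery — not the
historical conclusions of any real-data analysis. Counts that a real
analysis would report (numbers of filtered segments, variant-set sizes)
depend entirely on the deposited call sets and are exposed as outputs, not
asserted as constants.

## Defaults

| parameter | default | note |
| --- | --- | --- |
| segment filters | ≥ 30 comparable variants, ≥ 30% match rate | thresholds inclusive |
| LD expansion r² | 0.999 / 0.8 / 0.5 | within 1 Mb, phase preserved |
| ν floor | r² ≥ 0.2 within 1 Mb | else ν = 0 |
| common-variant MAF | > 0.05 | enrichment denominators |
| LD-score window | 1 Mb (bp mode) | no genetic map in the panel |
| jackknife | 200 blocks | grouped to whole LD blocks under GLS |
| MAF bins (signed background) | 5 equal-count | |
| direction test | p < 1e-8, prune r² = 1 | 5e-8/1e-6 and 0.8/0.5 supported |
| scan | 30 kb, ≥ 15 variants, r² > 0.5, marginal p < 1e-4 | |
| overlap null | 10,000 shuffles | +1-corrected empirical p |
| FDR | BH at 0.05 | throughout |
| MHC-like exclusion | configurable `(chrom, start, end)` | no fixed human coordinates in the synthetic world |
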