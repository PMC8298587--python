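# introgh2

Partitioned heritability and directional effects of archaic (Neanderthal)
introgression on complex traits, with a fully synthetic test bed.

## The scientific problem

Roughly 2% of the genome of people with Eurasian ancestry traces to
Neanderthal admixture. Two population-genetic questions follow for any
complex trait:

1. **How much trait heritability do introgressed regions and alleles carry?**
   Under a null of complete polygenicity, a set of variants covering a
   fraction `|c|/M` of common variants should explain the same fraction of
   SNP-heritability. Stratified LD-score regression (S-LDSC) tests this by
   regressing GWAS χ² statistics on stratified LD scores
   `ℓ(j,c) = Σ_{k∈c} r²_jk` and reporting the fold-enrichment

   ```
   Enrichment_c = (h²_(c) / h²) / (|c| / M)
   ```

   with block-jackknife uncertainty. Values below 1 ("1.28-fold depleted")
   indicate selection against trait-affecting introgressed variation.

2. **Do the surviving archaic alleles push traits in a consistent
   direction?** Two complementary tests: (i) orient genome-wide-significant
   GWAS Z-scores to the archaic(-linked) allele, LD-prune, and compare the
   positive/negative counts with a one-tailed χ² goodness-of-fit test;
   (ii) signed LD-profile (SLDP) regression, which estimates the
   genome-wide functional correlation `r_f` in

   ```
   E(α̂ | ν) = r_f · √(h²_g) · Rν
   ```

   where `α̂` are marginal trait effects from summary statistics, `ν` is the
   signed Neanderthal LD profile (each variant's maximum r² to an
   introgressed allele, signed by which allele rides the introgressed
   haplotype), and `R` is the reference-panel LD matrix. A signed
   minor-allele background model (five MAF bins) is projected out, and
   significance comes from an empirical block sign-flip null. A 30-kb
   sliding-window scan over the SLDP residuals then localizes the signal,
   and a shuffle test asks whether hit windows overlap putatively adaptive
   haplotypes more than expected.

The package is aimed at population-genetics methodologists: every stage is
exercised end to end on synthetic haplotype panels with planted
introgressed segments and GWAS summary statistics with known truth, so the
estimators' calibration and power can be verified offline.

## Layout

| module | contents |
| --- | --- |
| `introgh2.synthetic_data` | haplotype panels with block LD and planted introgression, Sprime-like call files, stratified polygenic GWAS simulation |
| `introgh2.annotations` | segment filtering/merging, nested variant sets (Altai/Vindija × EUR/any), LD expansion with phase, MAF strata, the signed LD profile ν |
| `introgh2.partitioned_h2` | stratified LD scores, the S-LDSC fit, block jackknife, fold-change rendering, trait QC, trait-group aggregation |
| `introgh2.directionality` | archaic orientation of Z-scores, greedy LD pruning, the χ² direction test, the SLDP GLS fit with its sign-flip null |
| `introgh2.window_scan` | sliding-window scan, merge/refit, filters, shuffle overlap test |
| `introgh2.formats`, `introgh2.pipeline`, `introgh2.cli` | file dialects, stage orchestration with provenance headers, the `introgh2` command line |

## Worked example

Simulate a trait in which introgressed variants are 3-fold enriched for
heritability, then recover the enrichment:

```python
import numpy as np, pandas as pd
from introgh2 import synthetic_data as sd, partitioned_h2 as ph2

cfg = sd.SimConfig(
    seed=42, n_haplotypes=400, n_variants=2000, n_blocks=40,
    segment_spec=tuple(sd.SegmentSpec(10_000, 10, 0.15) for _ in range(12)),
    gwas_n=200_000, h2_total=0.3,
    annotation_enrichment={"introgressed": 3.0},
)
panel = sd.simulate_panel(cfg)
membership = pd.DataFrame({
    "base": np.ones(panel.n_variants, dtype=int),
    "introgressed": panel.variants["archaic_flag"].astype(int),
})
truth, sumstats = sd.simulate_trait(panel, cfg, membership)
scores = ph2.compute_ld_scores(panel, membership, adjust=False)
fit = ph2.fit_sldsc(sumstats, scores, panel, membership, n_blocks=40)
row = fit.table.loc["introgressed"]
print(f"{row['enrichment']:.2f} (SE {row['se']:.2f}) -> "
      f"{ph2.fold_change(row['enrichment'])}")
```

prints

```
3.13 (SE 1.07) -> 3.13-fold enriched
```

i.e. the 120 introgressed variants (6% of sites) carry an estimated
3.13-fold share of heritability (this replicate's realized enrichment from
the drawn effects is 2.75; the jackknife SE is 1.07). Adding a directional
mean on the archaic alleles (`directional_mean={"introgressed": 0.02}`)
and fitting SLDP against the archaic LD profile on the same panel yields a
strongly positive functional correlation (`r_f = 28.35%`, empirical
`p = 5.0e-4` at 2,000 sign flips) and an archaic-oriented
genome-wide-significant count of 39 trait-increasing vs 0 trait-decreasing
alleles (χ² = 39.0, one-tailed p = 2.1e-10) — the uni-directional regime.
With the direction test's published-scale inputs (17 archaic alleles, 15
associated with one direction), `direction_test(n_pos=15, n_neg=2)` gives
χ² = 9.941 and one-tailed p = 8.1e-4.

The same workflow is available from the shell:

```sh
introgh2 run --config config.yaml --seed 3 --out results/
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch at a given
seed — simulation, Sprime-like file round trip, annotation construction,
LD scores, the S-LDSC fit, both directionality analyses, the window scan,
and the 10,000-shuffle overlap test — and writes its result JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Limits

The deposited call sets, reference panels, and biobank summary statistics
of a real analysis are deliberately out of scope; the synthetic world uses
a block-LD latent-Gaussian panel (no recombination maps, no demography) and
standardized-genotype effect sizes. See `docs/methods.md` for the model,
the estimator choices, and what the tests do and do not establish.
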