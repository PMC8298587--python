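"""Synthetic haplotype panels, introgression calls, and GWAS summary statistics.

The generator emulates the inputs of an introgression-heritability study:

* a phased diploid haplotype reference panel with block-structured LD
  (latent Gaussian threshold model, pairwise correlation ``exp(-decay * d)``
  within a block, ~0 across blocks);
* planted introgressed haplotype segments at controlled frequency whose
  carriers share all archaic alleles of the segment;
* Sprime-style per-population segment and per-variant call files;
* GWAS summary statistics drawn from a stratified polygenic model with
  per-annotation heritability enrichment, an optional directional mean on
  archaic-oriented alleles, LD-induced correlation of marginal effects, and
  sampling noise at a stated GWAS sample size.

All effects are on the standardized-genotype scale: a per-allele effect is
divided by sqrt(2 p (1-p)), so the per-variant variance contribution is
``beta_j ** 2`` and marginal effects are correlations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SegmentSpec",
    "SimConfig",
    "HaplotypePanel",
    "TraitTruth",
    "SummaryStats",
    "simulate_panel",
    "simulate_trait",
    "write_sprime_like",
    "make_toy_fixture",
    "FIXTURE_N_VARIANTS",
]

_BASES = np.array(["A", "C", "G", "T"])

#: Variant count of the deterministic toy fixture produced by make_toy_fixture.
FIXTURE_N_VARIANTS = 200


@dataclass(frozen=True)
class SegmentSpec:
    """One planted introgressed segment.

    length_bp
        Genomic span of the segment (0-based half-open interval).
    n_archaic
        Number of archaic alleles planted inside the segment.
    frequency
        Frequency of the archaic haplotype among panel haplotypes.
    """

    length_bp: int
    n_archaic: int
    frequency: float


@dataclass(frozen=True)
class SimConfig:
    """Stated world for one synthetic study.

    Defaults emulate a desk-scale European reference panel (1006 phased
    haplotypes, as in 503 diploid 1000G Europeans) with a mean GWAS sample
    size and total SNP-heritability matching a representative trait
    collection (N = 329,378, h2 = 0.19).
    """

    seed: int = 0
    n_haplotypes: int = 1006
    n_variants: int = 5000
    n_blocks: int = 100
    within_block_decay: float = 1e-4
    bp_spacing: int = 500
    segment_spec: tuple[SegmentSpec, ...] = ()
    gwas_n: int = 329_378
    h2_total: float = 0.19
    annotation_enrichment: dict[str, float] = field(default_factory=dict)
    directional_mean: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 <= self.h2_total <= 1.0:
            raise ValueError(f"h2_total must be in [0,1], got {self.h2_total}")
        if self.n_blocks > self.n_variants:
            raise ValueError("n_blocks must not exceed n_variants")
        if self.n_blocks < 1 or self.n_variants < 1 or self.n_haplotypes < 2:
            raise ValueError("panel dimensions out of range")
        if self.gwas_n <= 0:
            raise ValueError("gwas_n must be positive")
        if self.within_block_decay < 0:
            raise ValueError("within_block_decay must be non-negative")
        for i, seg in enumerate(self.segment_spec):
            if seg.length_bp <= 0:
                raise ValueError(f"segment {i}: length must be positive")
            if not 0.0 <= seg.frequency <= 1.0:
                raise ValueError(f"segment {i}: frequency must be in [0,1]")
            if seg.n_archaic < 1:
                raise ValueError(f"segment {i}: needs at least one archaic variant")
        if len(self.segment_spec) > self.n_blocks:
            raise ValueError("at most one planted segment per LD block")
        for name, e in self.annotation_enrichment.items():
            if e < 0:
                raise ValueError(f"enrichment for {name!r} must be >= 0")


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotype matrix plus variant and truth tables.

    genotypes
        ``(n_haplotypes, n_variants)`` int8 matrix; 1 = alternate allele.
    variants
        One row per variant: chrom, pos (1-based), id, ref, alt,
        archaic_flag, archaic_allele ("ref"/"alt"/""), alt_freq, block.
    segments_truth
        Planted segments: chrom, start, end (0-based half-open),
        n_archaic, frequency, and optional n_comparable / match_rate
        metadata used when emitting Sprime-like call files.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    segments_truth: pd.DataFrame

    @property
    def n_haplotypes(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def maf(self) -> np.ndarray:
        f = self.variants["alt_freq"].to_numpy()
        return np.minimum(f, 1.0 - f)

    def block_slices(self) -> list[slice]:
        blocks = self.variants["block"].to_numpy()
        out = []
        for b in np.unique(blocks):
            idx = np.flatnonzero(blocks == b)
            out.append(slice(int(idx[0]), int(idx[-1]) + 1))
        return out

    def block_corr(self, sl: slice) -> np.ndarray:
        g = self.genotypes[:, sl].astype(float)
        return np.corrcoef(g, rowvar=False).reshape(sl.stop - sl.start, -1)

    def r2(self, id_a: str, id_b: str) -> float:
        """Squared haplotype correlation between two variants (0 across blocks)."""
        idx = pd.Index(self.variants["id"])
        ia, ib = idx.get_loc(id_a), idx.get_loc(id_b)
        if self.variants["block"].iat[ia] != self.variants["block"].iat[ib]:
            return 0.0
        ga = self.genotypes[:, ia].astype(float)
        gb = self.genotypes[:, ib].astype(float)
        r = np.corrcoef(ga, gb)[0, 1]
        return float(r * r)

    def archaic_dosage(self, column: int) -> np.ndarray:
        """Per-haplotype indicator of carrying the archaic allele at a variant."""
        g = self.genotypes[:, column].astype(float)
        if self.variants["archaic_allele"].iat[column] == "ref":
            return 1.0 - g
        return g


@dataclass
class TraitTruth:
    """Ground truth of one simulated trait.

    beta is the true standardized effect oriented to the alternate allele;
    alpha = R beta is its noiseless marginal correlation (block-wise LD).
    realized_h2 is the sum of squared standardized effects; shares per
    annotation are exclusive sums over member variants.
    """

    beta: np.ndarray
    alpha: np.ndarray
    realized_h2: float
    realized_prop_h2: dict[str, float]


@dataclass
class SummaryStats:
    """GWAS summary statistics for one trait (LDSC sumstats dialect).

    table columns: SNP, A1 (effect allele), A2, N, Z.
    """

    trait: str
    table: pd.DataFrame


def _block_sizes(n_items: int, n_blocks: int) -> np.ndarray:
    sizes = np.full(n_blocks, n_items // n_blocks, dtype=int)
    sizes[: n_items % n_blocks] += 1
    return sizes


def simulate_panel(config: SimConfig) -> HaplotypePanel:
    """Draw a block-LD haplotype panel with planted introgressed segments.

    Each LD block lives on its own chromosome label.  Within a block a
    latent Gaussian with correlation ``exp(-decay * distance)`` is
    binarized at frequency-matched rank thresholds, so the alternate-allele
    count of every column is exact and no column is monomorphic.  Planted
    segments overwrite their archaic columns: carrier haplotypes (exactly
    ``round(frequency * n_haplotypes)`` of them) carry all archaic alleles.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    n_hap, n_var = config.n_haplotypes, config.n_variants
    sizes = _block_sizes(n_var, config.n_blocks)

    genotypes = np.empty((n_hap, n_var), dtype=np.int8)
    chroms: list[str] = []
    positions = np.empty(n_var, dtype=int)
    block_ids = np.empty(n_var, dtype=int)

    target_freq = rng.uniform(0.01, 0.5, size=n_var)
    start = 0
    for b, m in enumerate(sizes):
        sl = slice(start, start + m)
        pos = 1 + np.arange(m) * config.bp_spacing
        positions[sl] = pos
        chroms.extend([f"chr{b + 1}"] * m)
        block_ids[sl] = b
        dist = np.abs(pos[:, None] - pos[None, :])
        corr = np.exp(-config.within_block_decay * dist)
        # tiny jitter keeps the Cholesky stable for long, dense blocks
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(m))
        latent = rng.standard_normal((n_hap, m)) @ chol.T
        ranks = np.argsort(np.argsort(latent, axis=0), axis=0)
        counts = np.clip(np.round(target_freq[sl] * n_hap).astype(int), 1, n_hap - 1)
        genotypes[:, sl] = (ranks < counts[None, :]).astype(np.int8)
        start += m

    archaic_flag = np.zeros(n_var, dtype=bool)
    seg_rows = []
    for s, seg in enumerate(config.segment_spec):
        b = s  # one segment per block, blocks assigned in order
        sl = slice(int(np.sum(sizes[:b])), int(np.sum(sizes[: b + 1])))
        span_variants = seg.length_bp // config.bp_spacing + 1
        if seg.n_archaic > min(span_variants, sizes[b]):
            raise ValueError(
                f"segment {s}: {seg.n_archaic} archaic variants do not fit in "
                f"{seg.length_bp} bp at {config.bp_spacing} bp spacing"
            )
        n_carriers = int(round(seg.frequency * n_hap))
        if n_carriers <= 0 or n_carriers >= n_hap:
            raise ValueError(
                f"segment {s}: archaic frequency {seg.frequency} rounds to "
                f"{n_carriers} carriers out of {n_hap} haplotypes"
            )
        carriers = rng.choice(n_hap, size=n_carriers, replace=False)
        cols = np.arange(sl.start, sl.start + seg.n_archaic)
        genotypes[:, cols] = 0
        genotypes[np.ix_(carriers, cols)] = 1
        archaic_flag[cols] = True
        seg_start = int(positions[sl.start] - 1)
        seg_rows.append(
            {
                "chrom": f"chr{b + 1}",
                "start": seg_start,
                "end": seg_start + seg.length_bp,
                "n_archaic": seg.n_archaic,
                "frequency": seg.frequency,
            }
        )

    ref_idx = rng.integers(0, 4, size=n_var)
    alt_shift = rng.integers(1, 4, size=n_var)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]

    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "id": [f"rs{i + 1}" for i in range(n_var)],
            "ref": ref,
            "alt": alt,
            "archaic_flag": archaic_flag,
            "archaic_allele": np.where(archaic_flag, "alt", ""),
            "alt_freq": genotypes.mean(axis=0),
            "block": block_ids,
        }
    )
    segments = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "n_archaic", "frequency"]
    )
    return HaplotypePanel(genotypes=genotypes, variants=variants, segments_truth=segments)


def _effect_variance_weights(
    config: SimConfig, annotations: pd.DataFrame
) -> np.ndarray:
    """Per-variant variance multipliers hitting the target fold-enrichments.

    Targeted annotations get their fold-enrichment as a multiplier (product
    over memberships when annotations overlap); variants in no targeted
    annotation absorb the remainder so the total expected h2 is exact.
    """
    m = len(annotations)
    w = np.ones(m)
    targeted = np.zeros(m, dtype=bool)
    for name, enr in config.annotation_enrichment.items():
        if name not in annotations.columns:
            raise ValueError(f"enrichment target {name!r} not in annotation table")
        member = annotations[name].to_numpy().astype(bool)
        w[member] *= enr
        targeted |= member
    n_bg = int((~targeted).sum())
    s_targeted = w[targeted].sum()
    if n_bg == 0:
        if not np.isclose(s_targeted, m):
            raise ValueError("enrichment targets jointly infeasible: no background")
    else:
        w_bg = (m - s_targeted) / n_bg
        if w_bg < 0:
            raise ValueError(
                "enrichment targets jointly infeasible (implied background "
                f"variance {w_bg:.3g} < 0)"
            )
        w[~targeted] = w_bg
    return w


def simulate_trait(
    panel: HaplotypePanel,
    config: SimConfig,
    annotations: pd.DataFrame,
    trait: str = "sim_trait",
) -> tuple[TraitTruth, SummaryStats]:
    """Draw true effects and noisy GWAS summary statistics for one trait.

    ``beta_j ~ Normal(mu_j, h2/M * w_j)`` on the standardized scale, where
    ``w_j`` realizes the configured fold-enrichments and ``mu_j`` is the
    configured directional mean on the archaic-oriented allele (applied to
    archaic-flagged members; sign converted to alternate-allele
    orientation).  Marginal effects are ``alpha = R beta`` block-wise with
    R estimated from the panel; ``alphahat = alpha + eps`` with
    ``eps ~ N(0, R/N)`` block-wise, and ``Z = sqrt(N) * alphahat``.
    """
    config.validate()
    if len(annotations) != panel.n_variants:
        raise ValueError("annotation membership must cover all panel variants")
    rng = np.random.default_rng([config.seed, 23])
    m = panel.n_variants
    n = config.gwas_n

    w = _effect_variance_weights(config, annotations)
    sd = np.sqrt(config.h2_total / m * w)

    mu = np.zeros(m)
    flagged = panel.variants["archaic_flag"].to_numpy()
    orient = np.where(panel.variants["archaic_allele"].to_numpy() == "ref", -1.0, 1.0)
    for name, mean in config.directional_mean.items():
        if name not in annotations.columns:
            raise ValueError(f"directional mean target {name!r} not in annotation table")
        member = annotations[name].to_numpy().astype(bool) & flagged
        mu[member] += mean * orient[member]

    beta = mu + sd * rng.standard_normal(m)

    alpha = np.empty(m)
    alphahat = np.empty(m)
    for sl in panel.block_slices():
        corr = panel.block_corr(sl)
        alpha[sl] = corr @ beta[sl]
        # eigenvalue clipping: the panel-estimated R can be rank deficient
        vals, vecs = np.linalg.eigh(corr)
        vals = np.clip(vals, 0.0, None)
        chol_like = vecs * np.sqrt(vals)[None, :]
        eps = chol_like @ rng.standard_normal(sl.stop - sl.start) / np.sqrt(n)
        alphahat[sl] = alpha[sl] + eps

    realized_h2 = float(np.sum(beta**2))
    shares: dict[str, float] = {}
    for name in annotations.columns:
        member = annotations[name].to_numpy().astype(bool)
        shares[name] = float(np.sum(beta[member] ** 2) / realized_h2) if realized_h2 > 0 else 0.0

    truth = TraitTruth(
        beta=beta, alpha=alpha, realized_h2=realized_h2, realized_prop_h2=shares
    )
    table = pd.DataFrame(
        {
            "SNP": panel.variants["id"],
            "A1": panel.variants["alt"],
            "A2": panel.variants["ref"],
            "N": n,
            "Z": np.sqrt(n) * alphahat,
        }
    )
    return truth, SummaryStats(trait=trait, table=table)


def _segment_call_attrs(panel: HaplotypePanel) -> tuple[np.ndarray, np.ndarray]:
    seg = panel.segments_truth
    if "n_comparable" in seg.columns:
        n_comp = seg["n_comparable"].to_numpy(dtype=int)
    else:
        n_comp = seg["n_archaic"].to_numpy(dtype=int)
    if "match_rate" in seg.columns:
        rate = seg["match_rate"].to_numpy(dtype=float)
    else:
        rate = np.ones(len(seg))
    return n_comp, rate


def write_sprime_like(
    panel: HaplotypePanel,
    outdir: str | os.PathLike,
    populations: tuple[str, ...] = ("CEU",),
    altai_match_rate: float = 1.0,
    vindija_match_rate: float | None = None,
) -> dict[str, list[str]]:
    """Write Sprime-style per-population segment and variant call tables.

    Segment table: chrom, start, end, population, n_comparable, match_rate
    (extended BED).  Variant table: CHROM POS ID REF ALT SEGMENT ALLELE
    SCORE ALTAIMATCH VINDIJAMATCH with match status in
    {match, mismatch, notcomp}.  Within each segment the first
    ``round(rate * n)`` archaic variants are written "match" and the rest
    "mismatch", so the emitted tables are deterministic and round-trip
    losslessly through the readers.

    Returns a mapping {"segments": [...paths...], "variants": [...paths...]}.
    """
    if len(panel.segments_truth) == 0:
        raise ValueError("panel has no planted segments to write")
    if vindija_match_rate is None:
        vindija_match_rate = altai_match_rate
    os.makedirs(outdir, exist_ok=True)
    n_comp, seg_rate = _segment_call_attrs(panel)
    written: dict[str, list[str]] = {"segments": [], "variants": []}

    flagged = panel.variants[panel.variants["archaic_flag"]].reset_index(drop=True)
    seg_index = np.full(len(flagged), -1, dtype=int)
    for s, seg in panel.segments_truth.iterrows():
        inside = (
            (flagged["chrom"] == seg["chrom"])
            & (flagged["pos"] - 1 >= seg["start"])
            & (flagged["pos"] - 1 < seg["end"])
        )
        seg_index[inside.to_numpy()] = s

    def status_column(rate_scale: float) -> list[str]:
        out = ["mismatch"] * len(flagged)
        for s in range(len(panel.segments_truth)):
            rows = np.flatnonzero(seg_index == s)
            n_match = int(round(min(1.0, seg_rate[s] * rate_scale) * len(rows)))
            for k, row in enumerate(rows):
                out[row] = "match" if k < n_match else "mismatch"
        return out

    altai = status_column(altai_match_rate)
    vindija = status_column(vindija_match_rate)

    for pop in populations:
        seg_path = os.path.join(outdir, f"{pop}.segments.tsv")
        seg_df = pd.DataFrame(
            {
                "chrom": panel.segments_truth["chrom"],
                "start": panel.segments_truth["start"],
                "end": panel.segments_truth["end"],
                "population": pop,
                "n_comparable": n_comp,
                "match_rate": seg_rate,
            }
        )
        seg_df.to_csv(seg_path, sep="\t", index=False)
        written["segments"].append(seg_path)

        var_path = os.path.join(outdir, f"{pop}.variants.tsv")
        var_df = pd.DataFrame(
            {
                "CHROM": flagged["chrom"],
                "POS": flagged["pos"],
                "ID": flagged["id"],
                "REF": flagged["ref"],
                "ALT": flagged["alt"],
                "SEGMENT": seg_index,
                "ALLELE": np.where(flagged["archaic_allele"] == "alt", 1, 0),
                "SCORE": 100000,
                "ALTAIMATCH": altai,
                "VINDIJAMATCH": vindija,
            }
        )
        var_df.to_csv(var_path, sep="\t", index=False)
        written["variants"].append(var_path)
    return written


def toy_config() -> SimConfig:
    """Configuration of the deterministic 200-variant toy fixture.

    Five planted segments, one per block.  Their n_comparable / match_rate
    call metadata is the 5-segment filter fixture
    {(35,.5),(29,.5),(35,.29),(30,.30),(100,1.0)}: exactly three survive
    the default segment filters (>=30 comparable variants, >=30% match).
    """
    return SimConfig(
        seed=20_210_722,
        n_haplotypes=20,
        n_variants=FIXTURE_N_VARIANTS,
        n_blocks=5,
        within_block_decay=5e-5,
        bp_spacing=500,
        segment_spec=tuple(
            SegmentSpec(length_bp=4000, n_archaic=4, frequency=0.5) for _ in range(5)
        ),
        gwas_n=10_000,
        h2_total=0.5,
        annotation_enrichment={"introgressed": 2.0},
    )


def make_toy_fixture(
    outdir: str | os.PathLike | None = None,
) -> tuple[HaplotypePanel, SummaryStats, dict[str, list[str]]]:
    """Deterministic <=200-variant fixture with hand-checkable counts.

    Regenerated output is byte-identical.  When ``outdir`` is given the
    Sprime-like call files are written there; otherwise no files are
    produced and the files mapping is empty.
    """
    config = toy_config()
    panel = simulate_panel(config)
    fixture_attrs = [(35, 0.5), (29, 0.5), (35, 0.29), (30, 0.30), (100, 1.0)]
    panel.segments_truth["n_comparable"] = [a[0] for a in fixture_attrs]
    panel.segments_truth["match_rate"] = [a[1] for a in fixture_attrs]
    annotations = pd.DataFrame(
        {
            "base": np.ones(panel.n_variants, dtype=int),
            "introgressed": panel.variants["archaic_flag"].astype(int),
        }
    )
    truth, sumstats = simulate_trait(panel, config, annotations, trait="toy_trait")
    files: dict[str, list[str]] = {"segments": [], "variants": []}
    if outdir is not None:
        files = write_sprime_like(panel, outdir, populations=("CEU", "FIN"))
    return panel, sumstats, files
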