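"""Directional effects of archaic-introgressed alleles on traits.

Two complementary tests:

* at the extremes of the association distribution, genome-wide-significant
  variants are oriented to the archaic(-linked) allele, LD-pruned, and the
  positive/negative counts compared against a 50/50 expectation with a
  one-tailed chi-square goodness-of-fit test;
* genome-wide, signed LD-profile (SLDP) regression estimates the functional
  correlation r_f between marginal trait effects (alpha-hat from summary
  statistics) and each variant's aggregate tagging of the introgression
  annotation (R nu), by generalized least squares after projecting out a
  signed minor-allele background model in five MAF bins, with an empirical
  null from flipping the signs of nu in large contiguous blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import HaplotypePanel, SummaryStats

__all__ = [
    "DirectionTestResult",
    "SLDPResult",
    "orient_to_archaic",
    "threshold_and_prune",
    "direction_test",
    "adjust_direction_tests",
    "build_signed_background",
    "fit_sldp",
]


@dataclass
class DirectionTestResult:
    """One-tailed chi-square goodness-of-fit test against a 50/50 split."""

    trait: str
    n_pos: int
    n_neg: int
    chi2: float
    p_one_tailed: float
    q: float = np.nan
    p_cut: float | None = None
    prune_r2: float | None = None
    no_data: bool = False


@dataclass
class SLDPResult:
    """Signed LD-profile regression fit for one trait.

    r_f is the functional correlation in percent; p is empirical from the
    block sign-flip null (two-sided on |r_f|).  residuals holds per-variant
    residual alpha-hat and residual R nu after background projection,
    oriented to the Neanderthal-linked allele.
    """

    trait: str
    r_f: float
    z: float
    p: float
    residuals: pd.DataFrame
    m_regression: int
    q: float = np.nan
    null_r_f: np.ndarray = field(default_factory=lambda: np.empty(0))


def orient_to_archaic(
    sumstats: SummaryStats, expanded: pd.DataFrame
) -> pd.DataFrame:
    """Re-sign GWAS Z so positive means the archaic(-linked) allele increases the trait.

    ``expanded`` is an ``annotations.ld_expand`` result (columns proxy,
    linked_allele, r2, source).  The Z sign flips when the GWAS effect
    allele differs from the linked allele; rows where neither allele
    matches are dropped and counted in ``result.attrs["n_allele_mismatch"]``.
    Duplicate proxies resolve to the highest-r2 source.
    """
    exp = expanded.sort_values(["proxy", "r2"], ascending=[True, False], kind="mergesort")
    exp = exp.drop_duplicates(subset="proxy")
    merged = sumstats.table.merge(exp, left_on="SNP", right_on="proxy", how="inner")
    n_unmatched = len(exp) - len(merged)
    flip = merged["A1"] != merged["linked_allele"]
    valid = (~flip) | (merged["A2"] == merged["linked_allele"])
    n_mismatch = int((~valid).sum())
    merged = merged.loc[valid]
    z = np.where(merged["A1"] == merged["linked_allele"], merged["Z"], -merged["Z"])
    out = pd.DataFrame(
        {
            "id": merged["SNP"].to_numpy(),
            "z_archaic": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
            "r2": merged["r2"].to_numpy(),
        }
    )
    out.attrs["n_unmatched"] = n_unmatched
    out.attrs["n_allele_mismatch"] = n_mismatch
    return out.reset_index(drop=True)


def threshold_and_prune(
    assocs: pd.DataFrame, p_cut: float, prune_r2: float, ld_source
) -> pd.DataFrame:
    """Significance-threshold then greedily LD-prune oriented associations.

    Keeps rows with p < ``p_cut``; then, scanning by ascending p, keeps a
    variant iff its r2 to every already-kept variant is strictly below
    ``prune_r2`` (at prune_r2 = 1 only perfect proxies collapse).
    ``ld_source`` is a callable (id_a, id_b) -> r2, e.g. ``panel.r2``.
    """
    if not 0.0 < p_cut < 1.0:
        raise ValueError(f"p_cut must be in (0,1), got {p_cut}")
    if not 0.0 < prune_r2 <= 1.0:
        raise ValueError(f"prune_r2 must be in (0,1], got {prune_r2}")
    passed = assocs.loc[assocs["p"] < p_cut].sort_values(
        ["p", "id"], kind="mergesort"
    )
    kept: list[int] = []
    for row in passed.itertuples():
        if all(ld_source(row.id, passed.at[k, "id"]) < prune_r2 for k in kept):
            kept.append(row.Index)
    return passed.loc[kept].reset_index(drop=True)


def direction_test(
    pruned: pd.DataFrame | None = None,
    n_pos: int | None = None,
    n_neg: int | None = None,
    trait: str = "",
    p_cut: float | None = None,
    prune_r2: float | None = None,
) -> DirectionTestResult:
    """Chi-square goodness-of-fit test of archaic-allele effect directions.

    Counts may be given directly or derived from the pruned oriented
    associations (sign of z_archaic).  chi2 = sum((obs - E)^2 / E) with
    E = n/2; the one-tailed p is the tail in the majority direction,
    equal to the one-sided normal tail of (n_pos - n_neg) / sqrt(n).
    """
    if pruned is not None:
        n_pos = int((pruned["z_archaic"] > 0).sum())
        n_neg = int((pruned["z_archaic"] < 0).sum())
    if n_pos is None or n_neg is None:
        raise ValueError("provide either pruned associations or both counts")
    n = n_pos + n_neg
    if n == 0:
        return DirectionTestResult(
            trait, 0, 0, 0.0, 1.0, p_cut=p_cut, prune_r2=prune_r2, no_data=True
        )
    e = n / 2.0
    chi2 = (n_pos - e) ** 2 / e + (n_neg - e) ** 2 / e
    p = float(stats.norm.sf(abs(n_pos - n_neg) / np.sqrt(n)))
    return DirectionTestResult(trait, n_pos, n_neg, float(chi2), p, p_cut=p_cut, prune_r2=prune_r2)


def adjust_direction_tests(results: list[DirectionTestResult]) -> list[DirectionTestResult]:
    """Benjamini-Hochberg adjustment of one-tailed p across a trait family."""
    pvals = [r.p_one_tailed for r in results]
    if pvals:
        q = multipletests(pvals, method="fdr_bh")[1]
        for r, qi in zip(results, q):
            r.q = float(qi)
    return results


def build_signed_background(panel: HaplotypePanel, n_bins: int = 5) -> pd.DataFrame:
    """Signed minor-allele indicator annotations in equal-count MAF bins.

    Variants are ranked by MAF and split into ``n_bins`` equal-count bins;
    within its bin a variant gets +1 when the alternate allele is the minor
    allele (ties at 0.5 count as minor) and -1 otherwise, 0 elsewhere.
    Projecting these out of the SLDP regression absorbs genome-wide
    minor-allele directionality (negative selection, stratification).
    """
    if panel.n_variants < n_bins:
        raise ValueError(f"{panel.n_variants} variants cannot fill {n_bins} MAF bins")
    maf = panel.maf
    order = np.argsort(maf, kind="mergesort")
    sign = np.where(panel.variants["alt_freq"].to_numpy() <= 0.5, 1.0, -1.0)
    cols = {}
    for b, idx in enumerate(np.array_split(order, n_bins)):
        col = np.zeros(panel.n_variants)
        col[idx] = sign[idx]
        cols[f"maf_bin_{b + 1}"] = col
    return pd.DataFrame(cols)


def _nu_alt_oriented(profile: pd.DataFrame, panel: HaplotypePanel) -> np.ndarray:
    """Signed nu in alternate-allele orientation, aligned to panel order."""
    prof = profile.set_index("id").reindex(panel.variants["id"])
    nu = prof["nu"].to_numpy(dtype=float)
    linked = prof["linked_allele"].to_numpy()
    alt = panel.variants["alt"].to_numpy()
    sign = np.where(linked == alt, 1.0, -1.0)
    return np.where(nu > 0, sign * nu, 0.0)


def fit_sldp(
    sumstats: SummaryStats,
    profile: pd.DataFrame,
    panel: HaplotypePanel,
    background: pd.DataFrame | None = None,
    h2_g: float = 0.1,
    n_null: int = 10_000,
    null_blocks: int = 300,
    seed: int = 0,
    regression_ids: pd.Index | None = None,
    exclude: tuple[str, int, int] | None = None,
    trait: str | None = None,
) -> SLDPResult:
    """Generalized least-squares signed LD-profile regression.

    Fits E(alpha_hat | nu) = r_f * sqrt(h2_g) * R nu jointly with the
    signed background columns, where R is the block-diagonal LD matrix
    estimated from the panel and nu is unit-normalized internally.  With
    Cov(alpha_hat) proportional to R the GLS estimator reduces to
    theta = (A' R A)^{-1} A' alpha_hat for A = [nu, background], so no
    inverse of R is required.  The empirical p flips the signs of nu in
    ``null_blocks`` contiguous equal-count blocks ``n_null`` times.
    """
    if h2_g <= 0:
        raise ValueError(f"h2_g must be positive, got {h2_g}")
    if n_null < 1:
        raise ValueError("n_null must be at least 1")
    trait = sumstats.trait if trait is None else trait
    panel_idx = pd.Index(panel.variants["id"])
    mask = np.ones(panel.n_variants, dtype=bool)
    if regression_ids is not None:
        mask &= panel_idx.isin(pd.Index(regression_ids))
    if exclude is not None:
        chrom, start, end = exclude
        pos0 = panel.variants["pos"].to_numpy() - 1
        mask &= ~(
            (panel.variants["chrom"].to_numpy() == chrom) & (pos0 >= start) & (pos0 < end)
        )

    ss = sumstats.table.set_index("SNP").reindex(panel_idx)
    z = ss["Z"].to_numpy(dtype=float)
    n_gwas = ss["N"].to_numpy(dtype=float)
    # orient alpha-hat to the alternate allele
    flip = ss["A1"].to_numpy() == panel.variants["ref"].to_numpy()
    alphahat = np.where(flip, -z, z) / np.sqrt(n_gwas)
    mask &= np.isfinite(alphahat)

    nu = _nu_alt_oriented(profile, panel)
    if background is None:
        background = build_signed_background(panel)
    b_mat = background.to_numpy(dtype=float)

    rows = np.flatnonzero(mask)
    m_reg = len(rows)
    chroms = panel.variants["chrom"].to_numpy()
    alphahat_r = alphahat[rows]
    nu_r = nu[rows]
    b_r = b_mat[rows]

    def empty_result(extra_p: float = 1.0) -> SLDPResult:
        resid = pd.DataFrame(
            {
                "id": panel_idx[rows],
                "chrom": chroms[rows],
                "pos": panel.variants["pos"].to_numpy()[rows],
                "resid_alpha": alphahat_r,
                "resid_rnu": np.zeros(m_reg),
            }
        )
        return SLDPResult(trait, 0.0, 0.0, extra_p, resid, m_reg)

    norm = np.linalg.norm(nu_r)
    if norm == 0:
        return empty_result()
    nu_t = nu_r / norm

    # block-diagonal R restricted to regression variants
    blk_of = panel.variants["block"].to_numpy()[rows]
    r_blocks: list[tuple[np.ndarray, np.ndarray]] = []
    for b in np.unique(blk_of):
        sub = np.flatnonzero(blk_of == b)
        g = panel.genotypes[np.ix_(np.arange(panel.n_haplotypes), rows[sub])].astype(float)
        corr = np.corrcoef(g, rowvar=False).reshape(len(sub), len(sub))
        r_blocks.append((sub, corr))

    def r_matvec(v: np.ndarray) -> np.ndarray:
        out = np.empty_like(v)
        for sub, corr in r_blocks:
            out[sub] = corr @ v[sub]
        return out

    def r_matmat(v: np.ndarray) -> np.ndarray:
        out = np.empty_like(v)
        for sub, corr in r_blocks:
            out[sub] = corr @ v[sub]
        return out

    r_nu = r_matvec(nu_t)
    r_b = r_matmat(b_r)
    btrb = b_r.T @ r_b
    bta = b_r.T @ alphahat_r

    def gls(nu_vec: np.ndarray, r_nu_vec: np.ndarray | None = None) -> float:
        """Slope on the nu column of the joint GLS fit, in sqrt(h2) units."""
        g11 = float(nu_vec @ (r_nu_vec if r_nu_vec is not None else r_matvec(nu_vec)))
        g1b = nu_vec @ r_b
        gmat = np.block([[np.array([[g11]]), g1b[None, :]], [g1b[:, None], btrb]])
        rhs = np.concatenate([[nu_vec @ alphahat_r], bta])
        theta = np.linalg.lstsq(gmat, rhs, rcond=None)[0]
        return float(theta[0])

    slope = gls(nu_t, r_nu)
    r_f = slope / np.sqrt(h2_g)

    # sign-flip null: flip the marginal-effect vector in contiguous groups of
    # whole LD blocks.  Because only block inner products enter the
    # statistic this is the operational dual of flipping nu block-wise, and
    # with the background columns flipped consistently it is an exact
    # randomization test under per-block symmetry of alpha-hat; the design
    # cross-products stay fixed so each draw is a linear functional of the
    # signs.
    n_ld = len(r_blocks)
    k = min(null_blocks, n_ld)
    group_bounds = np.linspace(0, n_ld, k + 1).astype(int)
    masks = [
        np.concatenate([r_blocks[i][0] for i in range(group_bounds[g], group_bounds[g + 1])])
        for g in range(k)
    ]
    g11 = float(nu_t @ r_nu)
    g1b = nu_t @ r_b
    gmat = np.block([[np.array([[g11]]), g1b[None, :]], [g1b[:, None], btrb]])
    ginv_row = np.linalg.lstsq(gmat, np.eye(gmat.shape[0])[:, 0], rcond=None)[0]
    t_vec = np.array([nu_t[idx] @ alphahat_r[idx] for idx in masks])
    u_mat = np.stack([b_r[idx].T @ alphahat_r[idx] for idx in masks])  # k x n_bg
    rng = np.random.default_rng([seed, 37])
    signs = rng.choice([-1.0, 1.0], size=(n_null, k))
    null_rf = (ginv_row[0] * (signs @ t_vec) + (signs @ u_mat) @ ginv_row[1:]) / np.sqrt(h2_g)
    p_emp = float((1 + np.sum(np.abs(null_rf) >= abs(r_f))) / (n_null + 1))
    null_sd = null_rf.std()
    z_score = float(r_f / null_sd) if null_sd > 0 else 0.0

    # residuals after projecting out the background only, displayed in
    # Neanderthal-linked-allele orientation
    gamma = np.linalg.lstsq(btrb, bta, rcond=None)[0]
    resid_alpha = alphahat_r - r_b @ gamma
    delta = np.linalg.lstsq(btrb, b_r.T @ r_nu, rcond=None)[0]
    resid_rnu = r_nu - r_b @ delta
    orient = np.where(nu_r < 0, -1.0, 1.0)
    residuals = pd.DataFrame(
        {
            "id": panel_idx[rows],
            "chrom": chroms[rows],
            "pos": panel.variants["pos"].to_numpy()[rows],
            "resid_alpha": resid_alpha * orient,
            "resid_rnu": resid_rnu * orient,
        }
    ).reset_index(drop=True)

    return SLDPResult(
        trait=trait,
        r_f=100.0 * r_f,
        z=z_score,
        p=p_emp,
        residuals=residuals,
        m_regression=m_reg,
        null_r_f=100.0 * null_rf,
    )
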