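"""Localizing directional introgression signals along the genome.

Slides a 30-kb window centered on each regression variant over the
per-variant SLDP residuals, keeps windows where the Pearson correlation
between residual alpha-hat and residual R nu is strong (r^2 above a
threshold, either sign) with enough variants, merges overlapping windows
(recomputing r over the merged span), filters merged windows on a marginal
GWAS association and overlap with an archaic-matching allele, and tests
whether the surviving windows overlap putatively adaptive haplotypes more
than expected by resampling window identities from the scan universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OverlapTestResult",
    "scan_windows",
    "merge_and_refit",
    "filter_windows",
    "shuffle_overlap_test",
]


@dataclass
class OverlapTestResult:
    """Empirical overlap test of hit windows against an interval set."""

    observed: float
    null_mean: float
    p: float
    n_shuffles: int
    seed: int


def _window_r(resid: pd.DataFrame, rows: np.ndarray) -> float:
    x = resid["resid_rnu"].to_numpy()[rows]
    y = resid["resid_alpha"].to_numpy()[rows]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def scan_windows(
    residuals: pd.DataFrame,
    size: int = 30_000,
    min_n: int = 15,
    r2_min: float = 0.5,
) -> pd.DataFrame:
    """Candidate windows centered on each regression variant.

    The window around a variant at 1-based position ``pos`` is the 0-based
    half-open interval [pos-1-size/2, pos-1+size/2).  A candidate is kept
    iff it holds at least ``min_n`` regression variants and the squared
    window correlation exceeds ``r2_min`` (either sign).  Input must be
    position-sorted within chromosome.
    """
    half = size // 2
    rows = []
    for chrom, grp in residuals.groupby("chrom", sort=False):
        pos0 = grp["pos"].to_numpy() - 1
        if np.any(np.diff(pos0) < 0):
            raise ValueError(f"residual table not position-sorted on {chrom}")
        base = grp.index.to_numpy()
        for c in pos0:
            lo, hi = c - half, c + half
            first = np.searchsorted(pos0, lo, side="left")
            last = np.searchsorted(pos0, hi, side="left")
            inside = base[first:last]
            if len(inside) < min_n:
                continue
            r = _window_r(residuals, inside)
            if r2_min <= 0 or r * r > r2_min:
                rows.append((chrom, int(max(lo, 0)), int(hi), len(inside), r))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_variants", "r"])


def merge_and_refit(candidates: pd.DataFrame, residuals: pd.DataFrame) -> pd.DataFrame:
    """Coalesce overlapping candidate windows and recompute r over merged spans.

    Abutting (end == start) windows stay separate.  The recomputed merged-
    window correlation may fall below the scan threshold; it is not
    re-filtered here.
    """
    if len(candidates) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_variants", "r"])
    cand = candidates.sort_values(["chrom", "start", "end"], kind="mergesort")
    merged = []
    for chrom, grp in cand.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for _, row in grp.iterrows():
            if cur_s is None:
                cur_s, cur_e = row["start"], row["end"]
            elif row["start"] < cur_e:  # strict overlap only
                cur_e = max(cur_e, row["end"])
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = row["start"], row["end"]
        merged.append((chrom, cur_s, cur_e))
    rows = []
    for chrom, start, end in merged:
        grp = residuals.loc[residuals["chrom"] == chrom]
        pos0 = grp["pos"].to_numpy() - 1
        inside = grp.index.to_numpy()[(pos0 >= start) & (pos0 < end)]
        rows.append((chrom, int(start), int(end), len(inside), _window_r(residuals, inside)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_variants", "r"])


def filter_windows(
    hits: pd.DataFrame,
    assoc: pd.DataFrame,
    set1_sites: pd.DataFrame,
    p_cut: float = 1e-4,
) -> pd.DataFrame:
    """Keep merged windows with a marginal association and an archaic allele.

    ``assoc`` gives per-variant chrom, pos (1-based), p; ``set1_sites``
    gives chrom, pos of archaic-matching introgressed alleles.  A window
    survives iff its minimum marginal p is strictly below ``p_cut`` and it
    contains at least one archaic allele position.  Adds columns min_p and
    n_set1.
    """
    min_p = np.full(len(hits), np.nan)
    n_set1 = np.zeros(len(hits), dtype=int)
    for i, row in enumerate(hits.itertuples()):
        in_assoc = (
            (assoc["chrom"] == row.chrom)
            & (assoc["pos"] - 1 >= row.start)
            & (assoc["pos"] - 1 < row.end)
        )
        if in_assoc.any():
            min_p[i] = assoc.loc[in_assoc, "p"].min()
        in_set1 = (
            (set1_sites["chrom"] == row.chrom)
            & (set1_sites["pos"] - 1 >= row.start)
            & (set1_sites["pos"] - 1 < row.end)
        )
        n_set1[i] = int(in_set1.sum())
    out = hits.copy()
    out["min_p"] = min_p
    out["n_set1"] = n_set1
    keep = (out["min_p"] < p_cut) & (out["n_set1"] >= 1)
    return out.loc[keep.fillna(False)].reset_index(drop=True)


def _overlap_flags(windows: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Per-window indicator of sharing >= 1 base with any interval."""
    if len(intervals) == 0 or len(windows) == 0:
        return np.zeros(len(windows), dtype=bool)
    same = windows["chrom"].to_numpy()[:, None] == intervals["chrom"].to_numpy()[None, :]
    lo = windows["start"].to_numpy()[:, None] < intervals["end"].to_numpy()[None, :]
    hi = windows["end"].to_numpy()[:, None] > intervals["start"].to_numpy()[None, :]
    return (same & lo & hi).any(axis=1)


def shuffle_overlap_test(
    hits: pd.DataFrame,
    universe: pd.DataFrame,
    haplotype_intervals: pd.DataFrame,
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> OverlapTestResult:
    """Shuffle null for overlap of hit windows with an interval set.

    ``universe`` is every merged candidate window overlapping at least one
    archaic-matching allele (same construction as the hits, without the
    trait filter); hits must be a subset.  The observed statistic is the
    fraction of hits overlapping any interval (>= 1 shared base); each
    shuffle draws |hits| windows from the universe without replacement.
    The empirical p uses the +1 correction, so p >= 1/(n_shuffles+1).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be at least 1")
    if len(hits) > len(universe):
        raise ValueError("universe smaller than the hit set")
    # hits must come from the same scan: every hit lies inside the universe
    # (spans can differ when the universe was merged without the r2 filter)
    covered = _overlap_flags(hits, universe)
    if not covered.all():
        missing = hits.iloc[int(np.flatnonzero(~covered)[0])]
        raise ValueError(
            f"hit window ({missing['chrom']}, {missing['start']}, {missing['end']}) "
            "not covered by the universe"
        )
    overlap = _overlap_flags(universe, haplotype_intervals)
    n_hit = len(hits)
    observed = float(_overlap_flags(hits, haplotype_intervals).mean()) if n_hit else 0.0
    # drawing |hits| windows without replacement and counting overlapping ones
    # is exactly a hypergeometric draw over the universe's overlap marks
    rng = np.random.default_rng([seed, 53])
    n_good = int(overlap.sum())
    if n_hit:
        null = rng.hypergeometric(n_good, len(universe) - n_good, n_hit, size=n_shuffles) / n_hit
    else:
        null = np.zeros(n_shuffles)
    p = float((1 + np.sum(null >= observed)) / (n_shuffles + 1))
    return OverlapTestResult(
        observed=observed,
        null_mean=float(null.mean()),
        p=p,
        n_shuffles=n_shuffles,
        seed=seed,
    )
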