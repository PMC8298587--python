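"""Genomic partitions derived from Sprime-style introgression calls.

Turns per-population segment/variant call tables and a haplotype panel into
the annotations the downstream analyses consume: filtered and merged
introgressed segments, nested variant sets of decreasing stringency,
LD-expanded allele sets carrying phase, the nonintrogressed complement,
minor-allele-frequency strata, and the signed Neanderthal LD profile
(per-variant maximum r2 to an introgressed allele, signed by which allele
rides the introgressed haplotype).

Coordinate conventions: segments are 0-based half-open (BED); variant
positions are 1-based; a variant at position ``pos`` lies in segment
``[start, end)`` iff ``start <= pos - 1 < end``.  Filter thresholds are
inclusive ("at least").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import HaplotypePanel

__all__ = [
    "EUR_POPULATIONS",
    "VariantSet",
    "filter_segments",
    "merge_segments",
    "build_variant_sets",
    "ld_expand",
    "nonintrogressed_variants",
    "maf_stratify",
    "build_ld_profile",
]

logger = logging.getLogger(__name__)

#: European discovery subpopulations of the reference call set.
EUR_POPULATIONS = frozenset({"CEU", "TSI", "FIN", "GBR", "IBS"})

_MATCH_TOKENS = frozenset({"match", "mismatch", "notcomp"})

SET_NAMES = ("set1_altai_eur", "set2_altai_any", "set3_eur_any", "set4_any_any", "vindija_eur")


@dataclass
class VariantSet:
    """A named set of introgressed alleles.

    members: one row per variant id with its archaic allele (a base).
    provenance: discovery populations contributing members.
    """

    name: str
    members: pd.DataFrame
    provenance: frozenset[str] = field(default_factory=frozenset)

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.members["id"])

    def __len__(self) -> int:
        return len(self.members)


def filter_segments(
    segments: pd.DataFrame, min_putative: int = 30, min_match: float = 0.30
) -> pd.DataFrame:
    """Keep segments with >= min_putative comparable variants and >= min_match rate.

    Both thresholds are inclusive; input order is preserved.
    """
    for col in ("n_comparable", "match_rate"):
        if col not in segments.columns:
            raise ValueError(f"segment table lacks required column {col!r}")
        bad = segments.index[segments[col].isna()]
        if len(bad):
            raise ValueError(f"segment row {bad[0]} has missing {col!r}")
    keep = (segments["n_comparable"] >= min_putative) & (segments["match_rate"] >= min_match)
    return segments.loc[keep].copy()


def _chrom_dialect(chroms: pd.Series) -> str:
    prefixed = chroms.astype(str).str.startswith("chr")
    if prefixed.all():
        return "chr"
    if (~prefixed).all():
        return "plain"
    raise ValueError("mixed chromosome naming dialects (chr-prefixed and plain)")


def merge_segments(per_population: list[pd.DataFrame]) -> pd.DataFrame:
    """Union per-population segment sets, coalescing overlapping/abutting intervals.

    Abutting means ``end == start``; such intervals are joined.  Output is
    sorted by (chrom, start) and carries concatenated population provenance.
    """
    frames = [df for df in per_population if len(df)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "populations"])
    allseg = pd.concat(frames, ignore_index=True)
    _chrom_dialect(allseg["chrom"])
    if "population" not in allseg.columns:
        allseg = allseg.assign(population="")
    allseg = allseg.sort_values(["chrom", "start", "end"], kind="mergesort")
    out = []
    for chrom, grp in allseg.groupby("chrom", sort=True):
        cur_start = cur_end = None
        pops: list[str] = []
        for _, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end, pops = row["start"], row["end"], [str(row["population"])]
            elif row["start"] <= cur_end:  # overlap or abutting
                cur_end = max(cur_end, row["end"])
                pops.append(str(row["population"]))
            else:
                out.append((chrom, cur_start, cur_end, ",".join(sorted(set(pops)))))
                cur_start, cur_end, pops = row["start"], row["end"], [str(row["population"])]
        out.append((chrom, cur_start, cur_end, ",".join(sorted(set(pops)))))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "populations"])


def build_variant_sets(variant_tables: pd.DataFrame) -> dict[str, VariantSet]:
    """Assemble the nested introgressed variant sets from per-variant call rows.

    ``variant_tables`` concatenates per-population rows with columns
    ID REF ALT ALLELE ALTAIMATCH VINDIJAMATCH population.  Nesting by
    construction: set1 (EUR & Altai match) is contained in set2 (any pop &
    Altai match) and set3 (EUR, any status), both contained in set4 (any
    pop, any status); vindija_eur is EUR & Vindija match.
    """
    df = variant_tables.copy()
    for col in ("ID", "REF", "ALT", "ALLELE", "ALTAIMATCH", "VINDIJAMATCH", "population"):
        if col not in df.columns:
            raise ValueError(f"variant table lacks required column {col!r}")
    for col in ("ALTAIMATCH", "VINDIJAMATCH"):
        bad = set(df[col].unique()) - _MATCH_TOKENS
        if bad:
            raise ValueError(f"unknown match-status token(s) in {col}: {sorted(bad)}")
    df["archaic_allele"] = np.where(df["ALLELE"].astype(int) == 1, df["ALT"], df["REF"])
    is_eur = df["population"].isin(EUR_POPULATIONS)
    altai = df["ALTAIMATCH"] == "match"
    vindija = df["VINDIJAMATCH"] == "match"

    def collect(mask: pd.Series, name: str) -> VariantSet:
        sub = df.loc[mask, ["ID", "archaic_allele", "population"]]
        sub = sub.drop_duplicates(subset="ID")
        members = sub.rename(columns={"ID": "id"})[["id", "archaic_allele"]].reset_index(
            drop=True
        )
        return VariantSet(
            name=name,
            members=members,
            provenance=frozenset(df.loc[mask, "population"].unique()),
        )

    return {
        "set1_altai_eur": collect(is_eur & altai, "set1_altai_eur"),
        "set2_altai_any": collect(altai, "set2_altai_any"),
        "set3_eur_any": collect(is_eur, "set3_eur_any"),
        "set4_any_any": collect(pd.Series(True, index=df.index), "set4_any_any"),
        "vindija_eur": collect(is_eur & vindija, "vindija_eur"),
    }


def _member_columns(vset: VariantSet, panel: HaplotypePanel) -> pd.DataFrame:
    """Set members located in the panel, with column index and archaic dosage sign."""
    idx = pd.Index(panel.variants["id"])
    locs, alleles = [], []
    missing = 0
    for _, row in vset.members.iterrows():
        if row["id"] not in idx:
            missing += 1
            continue
        col = idx.get_loc(row["id"])
        ref = panel.variants["ref"].iat[col]
        alt = panel.variants["alt"].iat[col]
        if row["archaic_allele"] == alt:
            sign = 1
        elif row["archaic_allele"] == ref:
            sign = -1
        else:
            missing += 1
            continue
        locs.append(col)
        alleles.append(sign)
    if missing:
        logger.info("%d set members absent from panel (skipped)", missing)
    out = pd.DataFrame({"column": locs, "archaic_is_alt": alleles})
    out.attrs["n_missing"] = missing
    return out


def ld_expand(
    vset: VariantSet,
    panel: HaplotypePanel,
    r2_min: float,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """LD-expand a variant set, preserving the phase of the linked allele.

    Every panel variant with squared haplotype correlation r2 > ``r2_min``
    to a set member within ``window`` bp (same chromosome) is returned once
    with the allele in phase with the archaic allele; each source tags
    itself at r2 = 1.  Duplicate proxies keep the highest-r2 source.
    Monomorphic proxies (r2 undefined) are excluded and counted in
    ``result.attrs["n_monomorphic"]``.
    """
    if not 0.0 < r2_min <= 1.0:
        raise ValueError(f"r2_min must be in (0,1], got {r2_min}")
    members = _member_columns(vset, panel)
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    ref = panel.variants["ref"].to_numpy()
    alt = panel.variants["alt"].to_numpy()
    gstd = panel.genotypes.astype(float)
    gstd = (gstd - gstd.mean(axis=0)) / gstd.std(axis=0)
    n_hap = panel.n_haplotypes
    n_mono = 0

    rows = []
    for _, mrow in members.iterrows():
        col = int(mrow["column"])
        dos = panel.archaic_dosage(col)
        sd = dos.std()
        if sd == 0:
            n_mono += 1
            continue
        dstd = (dos - dos.mean()) / sd
        near = np.flatnonzero((chrom == chrom[col]) & (np.abs(pos - pos[col]) <= window))
        r = gstd[:, near].T @ dstd / n_hap
        r2 = r * r
        src = panel.variants["id"].iat[col]
        for j, k in enumerate(near):
            if k == col:
                rows.append((src, src, 1.0, alt[col] if mrow["archaic_is_alt"] == 1 else ref[col]))
            elif r2[j] > r2_min:
                linked = alt[k] if r[j] > 0 else ref[k]
                rows.append((src, panel.variants["id"].iat[k], float(r2[j]), linked))
    out = pd.DataFrame(rows, columns=["source", "proxy", "r2", "linked_allele"])
    out = out.sort_values(["proxy", "r2"], ascending=[True, False], kind="mergesort")
    out = out.drop_duplicates(subset="proxy").reset_index(drop=True)
    out.attrs["n_missing"] = members.attrs["n_missing"]
    out.attrs["n_monomorphic"] = n_mono
    return out


def nonintrogressed_variants(
    panel: HaplotypePanel,
    segments: pd.DataFrame,
    set4_expanded: pd.DataFrame,
) -> pd.Index:
    """Panel variants inside merged segments minus LD-expanded introgressed alleles.

    ``set4_expanded`` is an ``ld_expand`` result (typically of set 4 at
    r2 > 0.5); both its sources and proxies are removed.
    """
    pos0 = panel.variants["pos"].to_numpy() - 1
    chrom = panel.variants["chrom"].to_numpy()
    inside = np.zeros(panel.n_variants, dtype=bool)
    for _, seg in segments.iterrows():
        inside |= (chrom == seg["chrom"]) & (pos0 >= seg["start"]) & (pos0 < seg["end"])
    excluded = set(set4_expanded["proxy"]) | set(set4_expanded["source"])
    ids = panel.variants["id"]
    keep = inside & ~ids.isin(excluded).to_numpy()
    return pd.Index(ids[keep])


def maf_stratify(
    vset: VariantSet, panel: HaplotypePanel, breaks: list[float]
) -> dict[str, pd.Index]:
    """Partition set members present in the panel into MAF strata.

    Strata are delimited by ``breaks`` (sorted, in (0, 0.5]); a variant
    whose MAF equals a break goes to the upper stratum.  The reference
    analysis strata correspond to breaks {0.0052, 0.05, 0.21}.
    """
    breaks = sorted(breaks)
    if not breaks or breaks[0] <= 0 or breaks[-1] > 0.5:
        raise ValueError("breaks must be sorted and in (0, 0.5]")
    idx = pd.Index(panel.variants["id"])
    present = [v for v in vset.ids if v in idx]
    maf = panel.maf
    edges = [0.0, *breaks, 0.5]
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    labels[-1] = f"[{edges[-2]:g},0.5]"
    out: dict[str, pd.Index] = {lab: [] for lab in labels}
    for vid in present:
        col = idx.get_loc(vid)
        stratum = int(np.searchsorted(breaks, maf[col], side="right"))
        out[labels[stratum]].append(vid)
    return {lab: pd.Index(ids) for lab, ids in out.items()}


def build_ld_profile(
    vset: VariantSet,
    panel: HaplotypePanel,
    r2_floor: float = 0.2,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Signed Neanderthal LD profile: per panel variant, max r2 to a set member.

    nu is the maximum squared haplotype correlation to any set member
    within ``window`` bp, or 0 when that maximum falls below ``r2_floor``.
    ``linked_allele`` is the variant's allele in phase with the archaic
    allele of the argmax member; ties are broken by nearest member, then
    lowest member position.  A set member present in the panel gets nu = 1.
    """
    members = _member_columns(vset, panel)
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    ref = panel.variants["ref"].to_numpy()
    alt = panel.variants["alt"].to_numpy()
    m = panel.n_variants
    gstd = panel.genotypes.astype(float)
    gstd = (gstd - gstd.mean(axis=0)) / gstd.std(axis=0)
    n_hap = panel.n_haplotypes

    best_r2 = np.zeros(m)
    best_dist = np.full(m, np.inf)
    best_pos = np.full(m, np.inf)
    linked = np.array([""] * m, dtype=object)

    for _, mrow in members.iterrows():
        col = int(mrow["column"])
        dos = panel.archaic_dosage(col)
        sd = dos.std()
        if sd == 0:
            continue
        dstd = (dos - dos.mean()) / sd
        near = np.flatnonzero((chrom == chrom[col]) & (np.abs(pos - pos[col]) <= window))
        r = gstd[:, near].T @ dstd / n_hap
        r2 = np.clip(r * r, 0.0, 1.0)
        if col in near:
            r2[np.flatnonzero(near == col)[0]] = 1.0  # self tags exactly
        dist = np.abs(pos[near] - pos[col])
        for j, k in enumerate(near):
            better = r2[j] > best_r2[k] or (
                r2[j] == best_r2[k]
                and (dist[j] < best_dist[k] or (dist[j] == best_dist[k] and pos[col] < best_pos[k]))
            )
            if better:
                best_r2[k] = r2[j]
                best_dist[k] = dist[j]
                best_pos[k] = pos[col]
                linked[k] = alt[k] if r[j] > 0 else ref[k]
    nu = np.where(best_r2 >= r2_floor, best_r2, 0.0)
    linked = np.where(nu > 0, linked, "")
    return pd.DataFrame(
        {
            "id": panel.variants["id"],
            "chrom": chrom,
            "pos": pos,
            "nu": nu,
            "linked_allele": linked,
        }
    )
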