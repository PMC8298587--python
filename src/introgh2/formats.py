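"""Readers and writers for the text dialects the pipeline stages exchange.

Dialects: LDSC-style sumstats (SNP A1 A2 N Z, whitespace-delimited),
Sprime-like per-variant and segment tables, plain BED and extended BED,
LDSC annot tables, per-variant LD-score and residual tables, and pairwise
LD tables.  All writers emit a '#'-prefixed provenance header (package
version, config hash, seed) and stable column orders; all readers tolerate
extra trailing columns and skip '#' comment lines.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd

from .synthetic_data import SummaryStats

__all__ = [
    "provenance_header",
    "write_table",
    "read_table",
    "read_sumstats",
    "write_sumstats",
    "read_sprime_variants",
    "read_intervals",
    "write_bed",
    "write_annot",
    "read_residuals",
    "write_residuals",
]

_SUMSTATS_COLUMNS = ("SNP", "A1", "A2", "N", "Z")


def config_hash(config: object) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: int | None = None, config: object | None = None) -> list[str]:
    from . import __version__

    lines = [f"#introgh2_version={__version__}"]
    if config is not None:
        lines.append(f"#config_hash={config_hash(config)}")
    if seed is not None:
        lines.append(f"#seed={seed}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | os.PathLike,
    seed: int | None = None,
    config: object | None = None,
) -> None:
    """TSV writer with a provenance header; floats at 6 significant digits."""
    with open(path, "w") as fh:
        for line in provenance_header(seed=seed, config=config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | os.PathLike, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def read_sumstats(path: str | os.PathLike, trait: str | None = None) -> SummaryStats:
    """Read the LDSC sumstats dialect (whitespace-delimited SNP A1 A2 N Z).

    Rows with a missing Z are dropped and counted in
    ``result.table.attrs["n_dropped"]``.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#", dtype=str)
    for col in _SUMSTATS_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"sumstats file {path} lacks mandatory column {col!r}")
    z = pd.to_numeric(df["Z"], errors="coerce")
    n_dropped = int(z.isna().sum())
    keep = z.notna()
    table = pd.DataFrame(
        {
            "SNP": df.loc[keep, "SNP"],
            "A1": df.loc[keep, "A1"],
            "A2": df.loc[keep, "A2"],
            "N": pd.to_numeric(df.loc[keep, "N"]),
            "Z": z[keep],
        }
    ).reset_index(drop=True)
    table.attrs["n_dropped"] = n_dropped
    if trait is None:
        trait = os.path.splitext(os.path.basename(path))[0]
    return SummaryStats(trait=trait, table=table)


def write_sumstats(sumstats: SummaryStats, path: str | os.PathLike) -> None:
    sumstats.table.to_csv(path, sep="\t", index=False, columns=list(_SUMSTATS_COLUMNS))


def read_sprime_variants(path: str | os.PathLike, population: str | None = None) -> pd.DataFrame:
    """Read a Sprime-like per-variant call table.

    Population of discovery is taken from a ``population`` column if
    present, else from the argument, else from the file-name stem
    (``CEU.variants.tsv`` -> ``CEU``).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ("CHROM", "POS", "ID", "REF", "ALT", "SEGMENT", "ALLELE", "ALTAIMATCH", "VINDIJAMATCH")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"Sprime variant table {path} lacks column {col!r}")
    if "population" not in df.columns:
        if population is None:
            population = os.path.basename(path).split(".")[0]
        df["population"] = population
    return df


def read_intervals(path: str | os.PathLike, dialect: str | None = None) -> pd.DataFrame:
    """Read intervals as 0-based half-open, sorted per chromosome.

    ``dialect`` is "bed" (3+ columns, no header) or "sprime_segments"
    (header: chrom start end population n_comparable match_rate); when
    omitted it is sniffed from the first non-comment line.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if not line.startswith("#"):
                first = line
                break
    if dialect is None:
        dialect = "sprime_segments" if first.split("\t")[0] == "chrom" else "bed"
    if dialect == "sprime_segments":
        df = pd.read_csv(path, sep="\t", comment="#")
        for col in ("chrom", "start", "end", "population", "n_comparable", "match_rate"):
            if col not in df.columns:
                raise ValueError(f"segment table {path} lacks column {col!r}")
    elif dialect == "bed":
        df = pd.read_csv(
            path, sep=r"\s+", comment="#", header=None,
            names=["chrom", "start", "end"], usecols=[0, 1, 2],
        )
    else:
        raise ValueError(f"unknown interval dialect {dialect!r}")
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(f"{path}: end <= start at line {int(bad[0]) + 1}")
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | os.PathLike, extra: list[str] | None = None) -> None:
    """Write (extended) BED: chrom, start, end plus optional extra columns."""
    cols = ["chrom", "start", "end", *(extra or [])]
    df.to_csv(path, sep="\t", index=False, header=False, columns=cols, float_format="%.6g")


def write_annot(
    variants: pd.DataFrame, annotations: pd.DataFrame, path: str | os.PathLike
) -> None:
    """LDSC annot dialect: CHR BP SNP CM plus one column per annotation."""
    out = pd.DataFrame(
        {
            "CHR": variants["chrom"],
            "BP": variants["pos"],
            "SNP": variants["id"],
            "CM": 0.0,
        }
    )
    for col in annotations.columns:
        out[col] = annotations[col].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def write_residuals(residuals: pd.DataFrame, path: str | os.PathLike, **meta) -> None:
    out = pd.DataFrame(
        {
            "SNP": residuals["id"],
            "CHR": residuals["chrom"],
            "BP": residuals["pos"],
            "RESID_ALPHA": residuals["resid_alpha"],
            "RESID_RNU": residuals["resid_rnu"],
        }
    )
    write_table(out, path, **meta)


def read_residuals(path: str | os.PathLike) -> pd.DataFrame:
    df = read_table(path)
    return df.rename(
        columns={
            "SNP": "id",
            "CHR": "chrom",
            "BP": "pos",
            "RESID_ALPHA": "resid_alpha",
            "RESID_RNU": "resid_rnu",
        }
    )


def normalize_chroms(df: pd.DataFrame, style: str, column: str = "chrom") -> pd.DataFrame:
    """Force a single chromosome naming dialect ('chr' or 'plain')."""
    s = df[column].astype(str)
    if style == "chr":
        s = np.where(s.str.startswith("chr"), s, "chr" + s)
    elif style == "plain":
        s = s.str.removeprefix("chr")
    else:
        raise ValueError(f"unknown chromosome style {style!r}")
    out = df.copy()
    out[column] = s
    return out
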