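"""Pipeline orchestration: configuration, stage graph, provenance.

``run_pipeline`` executes the analysis stages in dependency order on a
synthetic study: simulate a panel and GWAS, derive introgression
annotations from the emitted Sprime-like call files (exercising the
readers), compute stratified LD scores, fit the partitioned-heritability
regression, run both direction-of-effect analyses, scan for directional
windows, and test their overlap with putatively adaptive intervals.
Every emitted table carries a provenance header (package version, config
hash, seed); identical configurations produce identical bytes.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotations as ann
from . import directionality as direc
from . import formats
from . import partitioned_h2 as ph2
from . import synthetic_data as synth
from . import window_scan as wscan

__all__ = ["RunConfig", "run_pipeline", "STAGE_ORDER", "STAGE_DEPS"]

STAGE_ORDER = (
    "simulate",
    "annotate",
    "ldscore",
    "h2",
    "direction",
    "sldp",
    "scan",
    "overlap_test",
)

STAGE_DEPS = {
    "simulate": (),
    "annotate": ("simulate",),
    "ldscore": ("annotate",),
    "h2": ("ldscore",),
    "direction": ("annotate",),
    "sldp": ("annotate",),
    "scan": ("sldp",),
    "overlap_test": ("scan",),
}

# All analysis defaults are the reference-study values: 30 putative variants /
# 30% match segment filters, r2 expansions {0.999, 0.8, 0.5}, 1 Mb windows,
# 0.2 nu floor, 200 jackknife blocks, 5 MAF bins, 30 kb / 15 variants / 0.5
# scan, 1e-4 marginal p, 10,000 shuffles, FDR 0.05.
_DEFAULTS: dict[str, dict] = {
    "simulate": {
        "n_haplotypes": 1006,
        "n_variants": 5000,
        "n_blocks": 100,
        "within_block_decay": 1e-4,
        "bp_spacing": 500,
        "n_segments": 8,
        "segment_length_bp": 10_000,
        "segment_n_archaic": 10,
        "segment_frequency": 0.1,
        # call-file metadata: comparable-site count and archaic match rate of
        # each emitted segment (Sprime-like segments typically carry tens to
        # hundreds of comparable sites and pass the 30/30% filters)
        "segment_n_comparable": 60,
        "segment_match_rate": 0.9,
        "gwas_n": 329_378,
        "h2_total": 0.19,
        "annotation_enrichment": {},
        "directional_mean": {},
    },
    "annotate": {
        "min_putative": 30,
        "min_match": 0.30,
        "r2_expand": [0.999, 0.8, 0.5],
        "window_bp": 1_000_000,
        "nu_floor": 0.2,
        "archaic": "altai",
    },
    "ldscore": {"window_bp": 1_000_000, "adjust": True},
    "h2": {"jackknife_blocks": 200, "common_maf": 0.05, "fdr_level": 0.05},
    "direction": {"p_cut": 1e-8, "prune_r2": 1.0},
    "sldp": {"n_null": 10_000, "null_blocks": 300, "h2_g": None, "maf_bins": 5},
    "scan": {"size": 30_000, "min_n": 15, "r2_min": 0.5, "p_cut": 1e-4},
    "overlap_test": {"n_shuffles": 10_000, "haplotype_bed": None},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Unknown stages or parameter keys are rejected; every stage's
    dependencies must also be requested.
    """

    stages: tuple[str, ...] = STAGE_ORDER
    seed: int = 0
    out_dir: str = "introgh2_out"
    params: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged: dict[str, dict] = {}
        for stage in STAGE_ORDER:
            merged[stage] = copy.deepcopy(_DEFAULTS[stage])
        for stage, overrides in self.params.items():
            if stage not in _DEFAULTS:
                raise ValueError(f"unknown stage {stage!r} in params")
            for key, val in overrides.items():
                if key not in _DEFAULTS[stage]:
                    raise ValueError(f"unknown parameter {key!r} for stage {stage!r}")
                merged[stage][key] = val
        self.params = merged
        for stage in self.stages:
            if stage not in STAGE_ORDER:
                raise ValueError(f"unknown stage {stage!r}")
            for dep in STAGE_DEPS[stage]:
                if dep not in self.stages:
                    raise ValueError(f"stage {stage!r} requires {dep!r} in the stage list")
        self._validate_domains()

    def _validate_domains(self) -> None:
        p = self.params
        if p["overlap_test"]["n_shuffles"] < 1:
            raise ValueError("overlap_test.n_shuffles must be at least 1")
        if p["sldp"]["n_null"] < 1:
            raise ValueError("sldp.n_null must be at least 1")
        if not 0 < p["annotate"]["min_match"] <= 1:
            raise ValueError("annotate.min_match must be in (0,1]")
        if p["scan"]["min_n"] < 1:
            raise ValueError("scan.min_n must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"stages", "seed", "out_dir", "params"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def as_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "seed": self.seed,
            "out_dir": self.out_dir,
            "params": self.params,
        }

    def provenance_dict(self) -> dict:
        """Config content that determines outputs (paths excluded)."""
        return {"stages": list(self.stages), "seed": self.seed, "params": self.params}


def _sim_config(config: RunConfig) -> synth.SimConfig:
    p = config.params["simulate"]
    specs = tuple(
        synth.SegmentSpec(
            length_bp=p["segment_length_bp"],
            n_archaic=p["segment_n_archaic"],
            frequency=p["segment_frequency"],
        )
        for _ in range(p["n_segments"])
    )
    return synth.SimConfig(
        seed=config.seed,
        n_haplotypes=p["n_haplotypes"],
        n_variants=p["n_variants"],
        n_blocks=p["n_blocks"],
        within_block_decay=p["within_block_decay"],
        bp_spacing=p["bp_spacing"],
        segment_spec=specs,
        gwas_n=p["gwas_n"],
        h2_total=p["h2_total"],
        annotation_enrichment=dict(p["annotation_enrichment"]),
        directional_mean=dict(p["directional_mean"]),
    )


def _write(df: pd.DataFrame, config: RunConfig, name: str) -> str:
    path = os.path.join(config.out_dir, name)
    formats.write_table(df, path, seed=config.seed, config=config.provenance_dict())
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and return the state bundle.

    The state maps stage products (panel, sumstats, variant sets, fits,
    window tables, ...) by name; emitted artifact paths are under
    ``state["artifacts"]``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    state: dict = {"artifacts": []}
    for stage in STAGE_ORDER:
        if stage in config.stages:
            _STAGES[stage](config, state)
    return state


def _stage_simulate(config: RunConfig, state: dict) -> None:
    p = config.params["simulate"]
    sim = _sim_config(config)
    panel = synth.simulate_panel(sim)
    if len(panel.segments_truth):
        panel.segments_truth["n_comparable"] = p["segment_n_comparable"]
        panel.segments_truth["match_rate"] = p["segment_match_rate"]
    membership = pd.DataFrame(
        {
            "base": np.ones(panel.n_variants, dtype=int),
            "introgressed": panel.variants["archaic_flag"].astype(int),
        }
    )
    truth, sumstats = synth.simulate_trait(panel, sim, membership, trait="sim_trait")
    files = synth.write_sprime_like(panel, config.out_dir, populations=("CEU", "FIN"))
    ss_path = os.path.join(config.out_dir, "sim_trait.sumstats")
    formats.write_sumstats(sumstats, ss_path)
    state.update(panel=panel, truth=truth, sumstats=sumstats, sprime_files=files)
    state["artifacts"] += files["segments"] + files["variants"] + [ss_path]
    state["artifacts"].append(_write(panel.variants, config, "panel.variants.tsv"))


def _stage_annotate(config: RunConfig, state: dict) -> None:
    p = config.params["annotate"]
    panel = state["panel"]
    seg_tables = [formats.read_intervals(f, "sprime_segments") for f in state["sprime_files"]["segments"]]
    filtered = [ann.filter_segments(t, p["min_putative"], p["min_match"]) for t in seg_tables]
    merged = ann.merge_segments(filtered)
    var_tables = pd.concat(
        [formats.read_sprime_variants(f) for f in state["sprime_files"]["variants"]],
        ignore_index=True,
    )
    vsets = ann.build_variant_sets(var_tables)
    key = "set1_altai_eur" if p["archaic"] == "altai" else "vindija_eur"
    expansions = {
        r2: ann.ld_expand(vsets[key], panel, r2_min=r2, window=p["window_bp"])
        for r2 in p["r2_expand"]
    }
    set4_exp = ann.ld_expand(vsets["set4_any_any"], panel, r2_min=0.5, window=p["window_bp"])
    nonintro = ann.nonintrogressed_variants(panel, merged, set4_exp)
    profile = ann.build_ld_profile(vsets[key], panel, r2_floor=p["nu_floor"], window=p["window_bp"])

    ids = pd.Index(panel.variants["id"])
    pos0 = panel.variants["pos"].to_numpy() - 1
    chrom = panel.variants["chrom"].to_numpy()
    in_region = np.zeros(panel.n_variants, dtype=bool)
    for _, seg in merged.iterrows():
        in_region |= (chrom == seg["chrom"]) & (pos0 >= seg["start"]) & (pos0 < seg["end"])
    membership = pd.DataFrame(
        {
            "base": np.ones(panel.n_variants, dtype=int),
            "neanderthal_region": in_region.astype(int),
            "introgressed_set1": ids.isin(vsets[key].ids).astype(int),
            "nonintrogressed": ids.isin(nonintro).astype(int),
        }
    )
    state.update(
        merged_segments=merged,
        variant_sets=vsets,
        expansions=expansions,
        profile=profile,
        membership=membership,
        nonintrogressed=nonintro,
    )
    state["artifacts"].append(_write(merged, config, "merged_segments.tsv"))
    annot_path = os.path.join(config.out_dir, "annotations.annot")
    formats.write_annot(panel.variants, membership, annot_path)
    state["artifacts"].append(annot_path)
    state["artifacts"].append(_write(profile, config, "ld_profile.tsv"))


def _stage_ldscore(config: RunConfig, state: dict) -> None:
    p = config.params["ldscore"]
    scores = ph2.compute_ld_scores(
        state["panel"], state["membership"], window=p["window_bp"], adjust=p["adjust"]
    )
    state["ldscores"] = scores
    out = scores.scores.copy()
    out.insert(0, "SNP", state["panel"].variants["id"].to_numpy())
    out["L2_total"] = scores.total
    state["artifacts"].append(_write(out, config, "ldscores.tsv"))


def _stage_h2(config: RunConfig, state: dict) -> None:
    # one model per annotation of interest on top of the base annotation;
    # the region/set/complement columns are exactly collinear jointly
    p = config.params["h2"]
    membership = state["membership"]
    fits: dict[str, ph2.PartitionResult] = {}
    rows = []
    for annot in [c for c in membership.columns if c != "base"]:
        cols = ["base", annot]
        scores = ph2.LDScoreTable(
            ids=state["ldscores"].ids,
            scores=state["ldscores"].scores[cols],
            total=state["ldscores"].total,
        )
        fit = ph2.fit_sldsc(
            state["sumstats"],
            scores,
            state["panel"],
            membership[cols],
            n_blocks=p["jackknife_blocks"],
            common_maf=p["common_maf"],
        )
        fits[annot] = fit
        row = fit.table.loc[annot].to_dict()
        row["annotation"] = annot
        row["h2_total"] = fit.h2
        row["fold_change"] = (
            ph2.fold_change(row["enrichment"]) if row["enrichment"] > 0 else "undefined"
        )
        rows.append(row)
    state["partition"] = fits
    out = pd.DataFrame(rows)[
        ["annotation", "tau", "h2_c", "prop_h2", "prop_snp", "enrichment", "se", "p", "h2_total", "fold_change"]
    ]
    state["artifacts"].append(_write(out, config, "h2_partition.tsv"))


def _stage_direction(config: RunConfig, state: dict) -> None:
    p = config.params["direction"]
    expansion = state["expansions"][max(state["expansions"])]  # tightest r2
    oriented = direc.orient_to_archaic(state["sumstats"], expansion)
    pruned = direc.threshold_and_prune(
        oriented, p_cut=p["p_cut"], prune_r2=p["prune_r2"], ld_source=state["panel"].r2
    )
    result = direc.direction_test(
        pruned, trait=state["sumstats"].trait, p_cut=p["p_cut"], prune_r2=p["prune_r2"]
    )
    direc.adjust_direction_tests([result])
    state["direction"] = result
    out = pd.DataFrame(
        [
            {
                "trait": result.trait,
                "n_pos": result.n_pos,
                "n_neg": result.n_neg,
                "chi2": result.chi2,
                "p_one_tailed": result.p_one_tailed,
                "q": result.q,
            }
        ]
    )
    state["artifacts"].append(_write(out, config, "direction_test.tsv"))


def _stage_sldp(config: RunConfig, state: dict) -> None:
    p = config.params["sldp"]
    h2_g = p["h2_g"]
    if h2_g is None:
        fits = state.get("partition")
        if fits:
            h2_g = max(next(iter(fits.values())).h2, 1e-3)
        else:
            h2_g = config.params["simulate"]["h2_total"]
    background = direc.build_signed_background(state["panel"], n_bins=p["maf_bins"])
    result = direc.fit_sldp(
        state["sumstats"],
        state["profile"],
        state["panel"],
        background=background,
        h2_g=h2_g,
        n_null=p["n_null"],
        null_blocks=p["null_blocks"],
        seed=config.seed,
    )
    state["sldp"] = result
    resid_path = os.path.join(config.out_dir, "sldp_residuals.tsv")
    formats.write_residuals(result.residuals, resid_path, seed=config.seed, config=config.provenance_dict())
    state["artifacts"].append(resid_path)
    out = pd.DataFrame(
        [{"trait": result.trait, "r_f_percent": result.r_f, "z": result.z, "p": result.p}]
    )
    state["artifacts"].append(_write(out, config, "sldp_fit.tsv"))


def _marginal_assoc(state: dict) -> pd.DataFrame:
    from scipy import stats as sps

    panel = state["panel"]
    ss = state["sumstats"].table.set_index("SNP").reindex(panel.variants["id"])
    return pd.DataFrame(
        {
            "chrom": panel.variants["chrom"].to_numpy(),
            "pos": panel.variants["pos"].to_numpy(),
            "p": 2.0 * sps.norm.sf(np.abs(ss["Z"].to_numpy(dtype=float))),
        }
    )


def _set1_sites(state: dict) -> pd.DataFrame:
    panel = state["panel"]
    key = [k for k in state["variant_sets"] if k.startswith("set1")][0]
    in_set = pd.Index(panel.variants["id"]).isin(state["variant_sets"][key].ids)
    return panel.variants.loc[in_set, ["chrom", "pos"]].reset_index(drop=True)


def _stage_scan(config: RunConfig, state: dict) -> None:
    p = config.params["scan"]
    resid = state["sldp"].residuals
    cands = wscan.scan_windows(resid, size=p["size"], min_n=p["min_n"], r2_min=p["r2_min"])
    merged = wscan.merge_and_refit(cands, resid)
    hits = wscan.filter_windows(merged, _marginal_assoc(state), _set1_sites(state), p_cut=p["p_cut"])
    # universe for the overlap null: same construction, no trait filter
    all_cands = wscan.scan_windows(resid, size=p["size"], min_n=p["min_n"], r2_min=0.0)
    universe = wscan.merge_and_refit(all_cands, resid)
    universe = wscan.filter_windows(universe, _marginal_assoc(state), _set1_sites(state), p_cut=1.1)
    state.update(window_hits=hits, window_universe=universe)
    path = os.path.join(config.out_dir, "window_hits.bed")
    formats.write_bed(hits, path, extra=["r", "n_variants", "min_p"])
    state["artifacts"].append(path)


def _stage_overlap_test(config: RunConfig, state: dict) -> None:
    p = config.params["overlap_test"]
    if p["haplotype_bed"] is not None:
        intervals = formats.read_intervals(p["haplotype_bed"], "bed")
    else:
        # default interval set: the planted introgressed segments
        intervals = state["panel"].segments_truth[["chrom", "start", "end"]]
    hits, universe = state["window_hits"], state["window_universe"]
    if len(hits) == 0 or len(universe) == 0:
        result = wscan.OverlapTestResult(0.0, 0.0, 1.0, p["n_shuffles"], config.seed)
    else:
        result = wscan.shuffle_overlap_test(
            hits, universe, intervals, n_shuffles=p["n_shuffles"], seed=config.seed
        )
    state["overlap"] = result
    out = pd.DataFrame(
        [
            {
                "observed": result.observed,
                "null_mean": result.null_mean,
                "p": result.p,
                "n_shuffles": result.n_shuffles,
            }
        ]
    )
    state["artifacts"].append(_write(out, config, "overlap_test.tsv"))


_STAGES = {
    "simulate": _stage_simulate,
    "annotate": _stage_annotate,
    "ldscore": _stage_ldscore,
    "h2": _stage_h2,
    "direction": _stage_direction,
    "sldp": _stage_sldp,
    "scan": _stage_scan,
    "overlap_test": _stage_overlap_test,
}
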