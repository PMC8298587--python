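import numpy as np
import pandas as pd
import pytest

from introgh2 import annotations as ann
from introgh2 import formats
from introgh2 import synthetic_data as sd


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """Deterministic 200-variant fixture with Sprime-like call files on disk."""
    outdir = tmp_path_factory.mktemp("toy_fixture")
    panel, sumstats, files = sd.make_toy_fixture(outdir)
    return panel, sumstats, files


@pytest.fixture(scope="session")
def toy_variant_sets(toy):
    _, _, files = toy
    tables = pd.concat(
        [formats.read_sprime_variants(f) for f in files["variants"]], ignore_index=True
    )
    return ann.build_variant_sets(tables)


def make_study(
    seed,
    n_haplotypes=400,
    n_variants=2000,
    n_blocks=40,
    n_segments=20,
    seg_len=10_000,
    seg_archaic=8,
    seg_freq=0.15,
    gwas_n=200_000,
    h2_total=0.3,
    enrichment=None,
    directional=None,
):
    """One synthetic study: panel with planted segments plus a simulated trait."""
    cfg = sd.SimConfig(
        seed=seed,
        n_haplotypes=n_haplotypes,
        n_variants=n_variants,
        n_blocks=n_blocks,
        segment_spec=tuple(
            sd.SegmentSpec(seg_len, seg_archaic, seg_freq) for _ in range(n_segments)
        ),
        gwas_n=gwas_n,
        h2_total=h2_total,
        annotation_enrichment=enrichment or {},
        directional_mean=directional or {},
    )
    panel = sd.simulate_panel(cfg)
    membership = pd.DataFrame(
        {
            "base": np.ones(panel.n_variants, dtype=int),
            "introgressed": panel.variants["archaic_flag"].astype(int),
        }
    )
    truth, sumstats = sd.simulate_trait(panel, cfg, membership)
    return cfg, panel, membership, truth, sumstats


def profile_from_panel(panel, tmpdir):
    """Archaic LD profile via the Sprime-like round trip."""
    files = sd.write_sprime_like(panel, tmpdir)
    tables = pd.concat(
        [formats.read_sprime_variants(f) for f in files["variants"]], ignore_index=True
    )
    vsets = ann.build_variant_sets(tables)
    return ann.build_ld_profile(vsets["set1_altai_eur"], panel), vsets
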