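"""Annotation construction: filters, merging, variant sets, LD expansion, nu."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from introgh2 import annotations as ann
from introgh2 import synthetic_data as sd


@pytest.fixture()
def filter_fixture():
    attrs = [(35, 0.5), (29, 0.5), (35, 0.29), (30, 0.30), (100, 1.0)]
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(5) * 1000,
            "end": np.arange(5) * 1000 + 500,
            "n_comparable": [a[0] for a in attrs],
            "match_rate": [a[1] for a in attrs],
        }
    )


class TestFilterSegments:
    def test_five_segment_fixture_keeps_three(self, filter_fixture):
        kept = ann.filter_segments(filter_fixture)
        assert len(kept) == 3
        assert list(kept["n_comparable"]) == [35, 30, 100]

    @pytest.mark.parametrize(
        "n_comp,rate,kept",
        [(29, 0.9, False), (30, 0.30, True), (30, 0.299, False), (1000, 1.0, True)],
    )
    def test_thresholds_inclusive(self, n_comp, rate, kept):
        seg = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10], "n_comparable": [n_comp], "match_rate": [rate]}
        )
        assert (len(ann.filter_segments(seg)) == 1) is kept

    def test_missing_field_names_row(self):
        seg = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "n_comparable": [40]})
        with pytest.raises(ValueError, match="match_rate"):
            ann.filter_segments(seg)


def _segments(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).assign(population="CEU")


class TestMergeSegments:
    def test_single_population_identity(self):
        seg = _segments([("chr1", 0, 100), ("chr1", 200, 300)])
        out = ann.merge_segments([seg])
        assert list(zip(out["chrom"], out["start"], out["end"])) == [
            ("chr1", 0, 100),
            ("chr1", 200, 300),
        ]

    def test_overlap_union(self):
        out = ann.merge_segments([_segments([("chr1", 100, 300)]), _segments([("chr1", 200, 400)])])
        assert list(zip(out["start"], out["end"])) == [(100, 400)]

    def test_abutting_coalesce_disjoint_preserved(self):
        out = ann.merge_segments([_segments([("chr1", 0, 10), ("chr1", 10, 20), ("chr1", 30, 40)])])
        assert list(zip(out["start"], out["end"])) == [(0, 20), (30, 40)]

    def test_mixed_chromosome_dialects_rejected(self):
        with pytest.raises(ValueError, match="dialect"):
            ann.merge_segments([_segments([("chr1", 0, 10), ("1", 20, 30)])])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 30)).map(lambda t: (t[0], t[0] + t[1])),
            min_size=1,
            max_size=12,
        ),
        st.randoms(use_true_random=False),
    )
    def test_idempotent_order_invariant_matches_oracle(self, ivals, rnd):
        """Merging equals a brute-force interval-union oracle, any input order."""
        segs = _segments([("chr1", a, b) for a, b in ivals])
        shuffled = segs.sample(frac=1, random_state=rnd.randrange(1000))
        out = ann.merge_segments([shuffled])
        # oracle: paint base pairs, read off maximal runs
        covered = np.zeros(100, dtype=bool)
        for a, b in ivals:
            covered[a:b] = True
        runs, i = [], 0
        while i < 100:
            if covered[i]:
                j = i
                while j < 100 and covered[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        assert list(zip(out["start"], out["end"])) == runs
        again = ann.merge_segments([out.rename(columns={"populations": "population"})])
        assert list(zip(again["start"], again["end"])) == runs


def _variant_rows():
    # 6 variants: hand enumeration gives set sizes (2, 3, 4, 6)
    rows = [
        # ID, REF, ALT, ALLELE, ALTAI, VINDIJA, pop
        ("v1", "A", "G", 1, "match", "match", "CEU"),      # sets 1-4, vindija
        ("v2", "C", "T", 1, "match", "mismatch", "GBR"),   # sets 1-4
        ("v3", "A", "C", 0, "match", "match", "CHB"),      # sets 2, 4
        ("v4", "G", "T", 1, "mismatch", "match", "TSI"),   # sets 3, 4, vindija
        ("v5", "A", "T", 1, "notcomp", "notcomp", "IBS"),  # sets 3, 4
        ("v6", "C", "G", 0, "mismatch", "notcomp", "CHB"), # set 4 only
    ]
    return pd.DataFrame(
        rows, columns=["ID", "REF", "ALT", "ALLELE", "ALTAIMATCH", "VINDIJAMATCH", "population"]
    )


class TestBuildVariantSets:
    def test_hand_enumerated_sizes(self):
        vsets = ann.build_variant_sets(_variant_rows())
        assert len(vsets["set1_altai_eur"]) == 2
        assert len(vsets["set2_altai_any"]) == 3
        assert len(vsets["set3_eur_any"]) == 4
        assert len(vsets["set4_any_any"]) == 6
        assert set(vsets["vindija_eur"].ids) == {"v1", "v4"}

    def test_nesting_invariant(self):
        vsets = ann.build_variant_sets(_variant_rows())
        s1, s2 = set(vsets["set1_altai_eur"].ids), set(vsets["set2_altai_any"].ids)
        s3, s4 = set(vsets["set3_eur_any"].ids), set(vsets["set4_any_any"].ids)
        assert s1 <= s2 <= s4 and s1 <= s3 <= s4

    def test_archaic_allele_resolved_from_allele_index(self):
        vsets = ann.build_variant_sets(_variant_rows())
        members = vsets["set4_any_any"].members.set_index("id")["archaic_allele"]
        assert members["v1"] == "G" and members["v3"] == "A"

    def test_eas_notcomp_only_in_set4(self):
        vsets = ann.build_variant_sets(_variant_rows())
        assert "v6" in set(vsets["set4_any_any"].ids)
        for name in ("set1_altai_eur", "set2_altai_any", "set3_eur_any", "vindija_eur"):
            assert "v6" not in set(vsets[name].ids)

    def test_unknown_status_token_rejected(self):
        rows = _variant_rows()
        rows.loc[0, "ALTAIMATCH"] = "maybe"
        with pytest.raises(ValueError, match="maybe"):
            ann.build_variant_sets(rows)

    def test_nesting_on_toy_fixture(self, toy_variant_sets):
        s = {k: set(v.ids) for k, v in toy_variant_sets.items()}
        assert s["set1_altai_eur"] <= s["set2_altai_any"] <= s["set4_any_any"]
        assert s["set1_altai_eur"] <= s["set3_eur_any"] <= s["set4_any_any"]


def hand_panel():
    """4-haplotype, 3-variant panel where proxy alleles track the archaic allele.

    v1 archaic (alt G), v2 in perfect phase with v1 (its alt always rides the
    archaic haplotype), v3 in perfect anti-phase (its ref rides it).
    """
    genotypes = np.array(
        [
            [1, 1, 0],
            [1, 1, 0],
            [0, 0, 1],
            [0, 0, 1],
        ],
        dtype=np.int8,
    )
    variants = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "pos": [100, 200, 300],
            "id": ["v1", "v2", "v3"],
            "ref": ["A", "C", "T"],
            "alt": ["G", "T", "A"],
            "archaic_flag": [True, False, False],
            "archaic_allele": ["alt", "", ""],
            "alt_freq": genotypes.mean(axis=0),
            "block": [0, 0, 0],
        }
    )
    return sd.HaplotypePanel(genotypes, variants, pd.DataFrame(columns=["chrom", "start", "end"]))


def one_member_set():
    return ann.VariantSet(
        "set1_altai_eur", pd.DataFrame({"id": ["v1"], "archaic_allele": ["G"]})
    )


class TestLDExpand:
    def test_phase_of_linked_allele_hand_computed(self):
        out = ann.ld_expand(one_member_set(), hand_panel(), r2_min=0.9)
        got = out.set_index("proxy")
        assert got.loc["v1", "r2"] == 1.0 and got.loc["v1", "linked_allele"] == "G"
        assert got.loc["v2", "r2"] == pytest.approx(1.0) and got.loc["v2", "linked_allele"] == "T"
        # v3's ALT anti-correlates, so its REF rides the archaic haplotype
        assert got.loc["v3", "linked_allele"] == "T"

    def test_no_proxies_returns_sources_only(self, toy):
        panel, _, _ = toy
        # a lone archaic variant from block 3's segment, threshold just below 1
        vset = ann.VariantSet(
            "set1_altai_eur",
            pd.DataFrame({"id": ["rs1"], "archaic_allele": [panel.variants["alt"].iloc[0]]}),
        )
        out = ann.ld_expand(vset, panel, r2_min=0.9999)
        proxies = set(out["proxy"])
        assert "rs1" in proxies
        # only the other planted archaic variants of the same segment are perfect proxies
        assert proxies <= {"rs1", "rs2", "rs3", "rs4"}

    def test_monotone_in_threshold(self, toy, toy_variant_sets):
        panel, _, _ = toy
        loose = set(ann.ld_expand(toy_variant_sets["set1_altai_eur"], panel, 0.5)["proxy"])
        tight = set(ann.ld_expand(toy_variant_sets["set1_altai_eur"], panel, 0.999)["proxy"])
        assert tight <= loose

    def test_bad_threshold_rejected(self, toy, toy_variant_sets):
        panel, _, _ = toy
        with pytest.raises(ValueError):
            ann.ld_expand(toy_variant_sets["set1_altai_eur"], panel, 0.0)


class TestNonintrogressed:
    def test_toy_counts(self):
        panel = hand_panel()
        segments = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [250]})
        expanded = pd.DataFrame(
            {"source": ["v1", "v1"], "proxy": ["v1", "v2"], "r2": [1.0, 1.0], "linked_allele": ["G", "T"]}
        )
        out = ann.nonintrogressed_variants(panel, segments, expanded)
        assert list(out) == []  # v1, v2 expanded away; v3 outside segment
        segments2 = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [400]})
        out2 = ann.nonintrogressed_variants(panel, segments2, expanded)
        assert list(out2) == ["v3"]

    def test_outside_segment_never_returned(self, toy):
        panel, _, _ = toy
        segments = panel.segments_truth[["chrom", "start", "end"]]
        empty_exp = pd.DataFrame(columns=["source", "proxy", "r2", "linked_allele"])
        out = ann.nonintrogressed_variants(panel, segments, empty_exp)
        pos0 = panel.variants.set_index("id").loc[out, "pos"] - 1
        assert (pos0 < 4000).all()  # all toy segments span [0, 4000)


class TestMafStratify:
    def test_boundary_goes_to_upper_stratum(self):
        panel = hand_panel()
        # v1 MAF 0.5, v2 0.5, v3 0.5 -- build a synthetic MAF instead
        panel.variants["alt_freq"] = [0.05, 0.3, 0.02]
        vset = ann.VariantSet(
            "s", pd.DataFrame({"id": ["v1", "v2", "v3"], "archaic_allele": ["G", "T", "A"]})
        )
        out = ann.maf_stratify(vset, panel, [0.05])
        assert set(out["[0.05,0.5]"]) == {"v1", "v2"}
        assert set(out["[0,0.05)"]) == {"v3"}

    def test_reference_breaks_partition_members(self, toy, toy_variant_sets):
        panel, _, _ = toy
        vset = toy_variant_sets["set4_any_any"]
        out = ann.maf_stratify(vset, panel, [0.0052, 0.05, 0.21])
        union = set().union(*[set(v) for v in out.values()])
        present = set(vset.ids) & set(panel.variants["id"])
        assert union == present
        sizes = [len(v) for v in out.values()]
        assert sum(sizes) == len(present)


class TestLDProfile:
    def test_member_self_nu_is_one(self, toy, toy_variant_sets):
        panel, _, _ = toy
        prof = ann.build_ld_profile(toy_variant_sets["set1_altai_eur"], panel)
        members = set(toy_variant_sets["set1_altai_eur"].ids) & set(panel.variants["id"])
        got = prof.set_index("id").loc[sorted(members), "nu"]
        assert (got == 1.0).all()

    def test_far_variants_zero(self, toy, toy_variant_sets):
        panel, _, _ = toy
        prof = ann.build_ld_profile(toy_variant_sets["set1_altai_eur"], panel, window=1000)
        far = prof[(prof["chrom"] == "chr1") & (prof["pos"] > 3000)]
        assert (far["nu"] == 0).all()

    def test_matches_brute_force_oracle(self, toy, toy_variant_sets):
        """nu equals a double-loop max over all (variant, member) pairs exactly."""
        panel, _, _ = toy
        vset = toy_variant_sets["set1_altai_eur"]
        prof = ann.build_ld_profile(vset, panel, r2_floor=0.2)
        idx = pd.Index(panel.variants["id"])
        g = panel.genotypes.astype(float)
        expected = np.zeros(panel.n_variants)
        for _, row in vset.members.iterrows():
            if row["id"] not in idx:
                continue
            col = idx.get_loc(row["id"])
            dos = panel.archaic_dosage(col)
            for k in range(panel.n_variants):
                if panel.variants["chrom"].iat[k] != panel.variants["chrom"].iat[col]:
                    continue
                if abs(panel.variants["pos"].iat[k] - panel.variants["pos"].iat[col]) > 10**6:
                    continue
                r = np.corrcoef(dos, g[:, k])[0, 1]
                r2 = 1.0 if k == col else min(r * r, 1.0)
                expected[k] = max(expected[k], r2)
        expected[expected < 0.2] = 0.0
        assert np.array_equal(prof["nu"].to_numpy(), expected)
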