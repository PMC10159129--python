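import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import scan_oracle
from micronet import extract_seed_site, group_mirnas_by_seed, scan_all, scan_utrs, targeted_fraction
from micronet.io import SequenceRecord
from micronet.simulate import plant_seed_site

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


class TestSeedExtraction:
    def test_seed_is_nt2_to_8_reverse_complemented(self):
        rec = SequenceRecord("m", "UAGCAGCACAUCAUGGUUUACA")
        # seed nt 2-8 = AGCAGCA -> DNA site TGCTGCT
        assert extract_seed_site(rec) == "TGCTGCT"

    def test_dna_alphabet_mature_accepted(self):
        assert extract_seed_site(SequenceRecord("m", "TAGCAGCACATC")) == "TGCTGCT"

    def test_too_short_mature_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            extract_seed_site(SequenceRecord("m", "UAGCAGC"))

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTU"):
            extract_seed_site(SequenceRecord("m", "UAGXAGCACAUC"))

    def test_mirnas_differing_after_position_8_share_the_site(self):
        a = SequenceRecord("mir-30a-3p", "CUUUCAGUCGGAUGUUUACAGC")
        b = SequenceRecord("mir-30e-3p", "CUUUCAGUCGGAUGUUUACAAU")
        assert extract_seed_site(a) == extract_seed_site(b)
        groups = group_mirnas_by_seed([a, b])
        assert list(groups.values()) == [["mir-30a-3p", "mir-30e-3p"]]


class TestScan:
    def test_single_match_with_offset(self):
        table = scan_utrs("m", "TGCTGCT", [SequenceRecord("g1", "AAATGCTGCTAA")])
        assert table.to_dict("records") == [
            {"mirna_id": "m", "seed7": "TGCTGCT", "gene_id": "g1", "n_sites": 1, "offsets": "3"}
        ]

    def test_no_match_means_absent_row(self):
        assert scan_utrs("m", "TGCTGCT", [SequenceRecord("g1", "TTTTTTTTTT")]).empty

    def test_overlapping_occurrences_counted(self):
        # AAAAAAA occurs at offsets 0..3 in A*10
        table = scan_utrs("m", "AAAAAAA", [SequenceRecord("g", "A" * 10)])
        assert table.loc[0, "n_sites"] == 4
        assert table.loc[0, "offsets"] == "0,1,2,3"

    def test_ambiguous_base_never_matches(self):
        assert scan_utrs("m", "TGCTGCT", [SequenceRecord("g", "AATGCTGNTAA")]).empty

    def test_isoforms_pool_to_parent_gene(self):
        utrs = [SequenceRecord("G.1", "AATGCTGCT"), SequenceRecord("G.2", "TGCTGCTAA")]
        table = scan_utrs("m", "TGCTGCT", utrs)
        assert table.gene_id.tolist() == ["G"]
        assert table.loc[0, "offsets"] == "0,2"

    def test_case_and_u_normalization_on_scan(self):
        a = scan_utrs("m", "TGCTGCT", [SequenceRecord("g", "aaUGCUGCUaa".upper())])
        b = scan_utrs("m", "TGCTGCT", [SequenceRecord("g", "AATGCTGCTAA")])
        assert a.loc[0, "offsets"] == b.loc[0, "offsets"]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(utr=dna, seed=st.integers(0, 2**31 - 1))
    def test_offsets_equal_position_by_position_oracle(self, utr, seed):
        rng = np.random.default_rng(seed)
        site = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 7)])
        table = scan_utrs("m", site, [SequenceRecord("g", utr)])
        got = [int(o) for o in table.loc[0, "offsets"].split(",")] if len(table) else []
        assert got == scan_oracle(utr, site)


class TestPlantSeedSite:
    def test_direct_application_of_definition(self):
        assert plant_seed_site("AAAAAAAAAA", "AGCAGCA", 0) == "TGCTGCTAAA"

    def test_offset_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            plant_seed_site("ACGT", "AGCAGCA", 0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_round_trip_scan_finds_planted_offset(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(30, 120))
        utr = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
        mature = "".join(np.array(list("ACGU"))[rng.integers(0, 4, 22)])
        offset = int(rng.integers(0, length - 6))
        planted = plant_seed_site(utr, mature[1:8], offset)
        assert len(planted) == length
        site = extract_seed_site(SequenceRecord("m", mature))
        table = scan_utrs("m", site, [SequenceRecord("g", planted)])
        offsets = [int(o) for o in table.loc[0, "offsets"].split(",")]
        assert offset in offsets


def _matches_for(targets_by_mirna):
    rows = [
        {"mirna_id": m, "seed7": "NNNNNNN", "gene_id": g, "n_sites": 1, "offsets": "0"}
        for m, genes in targets_by_mirna.items()
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "seed7", "gene_id", "n_sites", "offsets"])


class TestTargetedFraction:
    def test_reported_counts_reproduce_published_percentages(self):
        degs = [f"deg{i:03d}" for i in range(432)]
        # overlap pattern realising the published union of 214 targeted DEGs
        sets = {
            "mir-15b": degs[:125],
            "mir-30a-3p/mir-30e-3p": degs[84:214],
            "mir-7142-3p": degs[:54],
        }
        assert len(set().union(*map(set, sets.values()))) == 214
        matches = _matches_for(sets)
        out = targeted_fraction(matches, degs, {k: [k] for k in sets}).set_index("mirna_group")
        assert out.loc["mir-15b", "n_targeted_degs"] == 125
        assert out.loc["mir-15b", "pct_of_degs"] == 28.94
        assert out.loc["mir-30a-3p/mir-30e-3p", "pct_of_degs"] == 30.09
        assert out.loc["mir-7142-3p", "pct_of_degs"] == 12.50
        assert out.loc["all_de_mirnas", "n_targeted_degs"] == 214
        assert out.loc["all_de_mirnas", "pct_of_degs"] == 49.54

    def test_zero_targets_zero_percent(self):
        out = targeted_fraction(_matches_for({}), ["g1", "g2"], ["m1"])
        assert (out.pct_of_degs == 0.0).all()

    def test_rounding_is_half_up(self):
        # 1/800 = 0.125% -> 0.13 under half-up (0.12 under banker's rounding)
        out = targeted_fraction(
            _matches_for({"m": ["g0"]}), [f"g{i}" for i in range(800)], ["m"]
        ).set_index("mirna_group")
        assert out.loc["m", "pct_of_degs"] == 0.13

    def test_seed_group_pools_distinct_members(self):
        matches = _matches_for({"a": ["g1"], "b": ["g2"]})
        out = targeted_fraction(matches, ["g1", "g2", "g3", "g4"], {"a/b": ["a", "b"]})
        assert out.set_index("mirna_group").loc["a/b", "n_targeted_degs"] == 2

    def test_empty_de_genes_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            targeted_fraction(_matches_for({}), [], ["m"])


def test_scan_all_combines_per_mirna_tables(small_sim):
    _, sim = small_sim
    de_mirnas = [r for r in sim.mirnas if r.id in sim.truth.true_de_mirna]
    table = scan_all(de_mirnas, sim.utrs)
    assert set(table.mirna_id) <= set(sim.truth.true_de_mirna)
    assert (table.n_sites >= 1).all()
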