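"""Zotu community summaries: composition, ranking, active-taxon calls."""

import numpy as np
import pandas as pd
import pytest

from nsip.community_summary import (
    ZotuTable,
    active_taxa,
    clade_composition,
    relative_abundance,
    top_n_taxa,
)


def table_from_counts(counts: dict[str, list[int]], zotus, clades, genera=None):
    idx = pd.Index(zotus, name="zotu")
    cdf = pd.DataFrame(counts, index=idx)
    meta = pd.DataFrame(
        {"fraction_class": ["HF"] * len(cdf.columns)},
        index=pd.Index(cdf.columns, name="sample"),
    )
    tax = pd.DataFrame(
        {"clade": clades, "genus": genera or ["g"] * len(zotus)}, index=idx
    )
    return ZotuTable(counts=cdf, metadata=meta, taxonomy=tax)


class TestRelativeAbundance:
    def test_single_zotu_is_unity(self):
        t = table_from_counts({"s1": [17]}, ["Zotu1"], ["A"])
        assert relative_abundance(t, ["s1"]).iloc[0] == 1.0

    def test_simple_proportions(self):
        t = table_from_counts({"s1": [25, 75]}, ["Zotu1", "Zotu2"], ["A", "B"])
        rel = relative_abundance(t, ["s1"])
        assert rel.tolist() == pytest.approx([0.25, 0.75])

    def test_invariant_under_sample_duplication(self):
        t = table_from_counts(
            {"s1": [10, 30], "s2": [10, 30]}, ["Zotu1", "Zotu2"], ["A", "B"]
        )
        rel_one = relative_abundance(t, ["s1"])
        rel_two = relative_abundance(t, ["s1", "s2"])
        assert rel_one.tolist() == pytest.approx(rel_two.tolist())

    def test_empty_group_rejected(self):
        t = table_from_counts({"s1": [1]}, ["Zotu1"], ["A"])
        with pytest.raises(ValueError):
            relative_abundance(t, [])


class TestCladeComposition:
    def test_reproduces_constructed_percentages(self):
        # counts proportional to the six AOA clade percentages
        pct = [38.4, 57.8, 3.6, 0.2, 0.04, 0.01]
        counts = [int(round(p * 10000)) for p in pct]
        clades = ["NS-Alpha", "NS-Gamma", "NS-Zeta", "NT-Alpha", "NS-Beta", "NS-Delta"]
        t = table_from_counts({"s1": counts}, [f"Zotu{i}" for i in range(6)], clades)
        comp = clade_composition(t, ["s1"])
        # the printed percentages sum to 100.05, so proportional counts
        # reproduce them only to that internal rounding (~0.03)
        for clade, expected in zip(clades, pct):
            assert comp.percent[clade] == pytest.approx(expected, abs=0.05)

    def test_single_clade_hundred_percent(self):
        t = table_from_counts({"s1": [3, 9]}, ["Zotu1", "Zotu2"], ["A", "A"])
        assert clade_composition(t, ["s1"]).percent["A"] == pytest.approx(100.0)

    def test_thirty_seventy_split(self):
        t = table_from_counts({"s1": [30, 70]}, ["Zotu1", "Zotu2"], ["A", "B"])
        comp = clade_composition(t, ["s1"])
        assert comp.percent["A"] == pytest.approx(30.0)
        assert comp.percent["B"] == pytest.approx(70.0)

    def test_percentages_sum_to_hundred(self, small_zotu_table):
        for group in (["hf_a", "hf_b"], ["light_a"], list(small_zotu_table.counts.columns)):
            comp = clade_composition(small_zotu_table, group)
            assert comp.percent.sum() == pytest.approx(100.0, abs=0.01)

    def test_absent_clade_reported_as_zero(self, small_zotu_table):
        comp = clade_composition(small_zotu_table, ["hf_a", "hf_b"])
        assert comp.percent["NT-Alpha"] == 0.0


class TestTopN:
    def test_top_one_is_most_abundant(self):
        t = table_from_counts({"s1": [5, 10, 1]}, ["ZotuA", "ZotuB", "ZotuC"], list("XYZ"))
        assert list(top_n_taxa(t, ["s1"], 1).index) == ["ZotuB"]

    def test_n_larger_than_taxa_returns_all(self):
        t = table_from_counts({"s1": [5, 10]}, ["ZotuA", "ZotuB"], ["X", "Y"])
        assert len(top_n_taxa(t, ["s1"], 10)) == 2

    def test_tie_at_rank_breaks_lexicographically(self):
        for zotus in (["ZotuA", "ZotuB", "ZotuC"], ["ZotuC", "ZotuB", "ZotuA"]):
            t = table_from_counts({"s1": [10, 10, 10]}, zotus, list("XYZ"))
            top2 = list(top_n_taxa(t, ["s1"], 2).index)
            assert top2 == ["ZotuA", "ZotuB"]

    def test_matches_full_sort_oracle_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = int(rng.integers(3, 12))
            zotus = [f"Zotu{i}" for i in range(m)]
            counts = rng.integers(0, 50, m).tolist()
            if sum(counts) == 0:
                counts[0] = 1
            t = table_from_counts({"s1": counts}, zotus, ["c"] * m)
            n = int(rng.integers(1, m + 1))
            got = list(top_n_taxa(t, ["s1"], n).index)
            total = sum(counts)
            oracle = sorted(zotus, key=lambda z: (-counts[zotus.index(z)] / total, z))[:n]
            assert got == oracle

    def test_genus_rollup(self, small_zotu_table):
        top = top_n_taxa(small_zotu_table, ["hf_a", "hf_b"], 2, level="genus")
        assert top.index[0] == "g1"
        assert top.iloc[0] == pytest.approx(140 / 200)


class TestActiveTaxa:
    def test_identical_groups_active_but_not_enriched(self):
        t = table_from_counts(
            {"hf": [50, 49, 1], "ref": [50, 49, 1]},
            ["Zotu1", "Zotu2", "Zotu3"],
            list("ABC"),
        )
        out = active_taxa(t, ["hf"], ["ref"], min_abund=0.01, fold=2.0)
        assert out["active"].tolist() == [True, True, True]
        assert not out["enriched"].any()

    def test_fourfold_enrichment_flagged(self):
        t = table_from_counts(
            {"hf": [40, 60], "ref": [10, 90]}, ["Zotu1", "Zotu2"], ["A", "B"]
        )
        out = active_taxa(t, ["hf"], ["ref"])
        assert bool(out.loc["Zotu1", "active"]) and bool(out.loc["Zotu1", "enriched"])

    def test_absent_from_hf_never_active(self):
        t = table_from_counts(
            {"hf": [100, 0], "ref": [1, 99]}, ["Zotu1", "Zotu2"], ["A", "B"]
        )
        out = active_taxa(t, ["hf"], ["ref"], min_abund=0.0)
        assert not bool(out.loc["Zotu2", "active"])
        assert not bool(out.loc["Zotu2", "enriched"])

    def test_reference_zero_enriched_iff_active(self):
        t = table_from_counts(
            {"hf": [30, 70], "ref": [0, 100]}, ["Zotu1", "Zotu2"], ["A", "B"]
        )
        out = active_taxa(t, ["hf"], ["ref"])
        assert bool(out.loc["Zotu1", "enriched"])

    def test_invariant_under_uniform_rescaling(self):
        base = {"hf": [40, 60], "ref": [10, 90]}
        scaled = {"hf": [400, 600], "ref": [30, 270]}
        zotus, clades = ["Zotu1", "Zotu2"], ["A", "B"]
        a = active_taxa(table_from_counts(base, zotus, clades), ["hf"], ["ref"])
        b = active_taxa(table_from_counts(scaled, zotus, clades), ["hf"], ["ref"])
        pd.testing.assert_frame_equal(a, b)


class TestZotuTableValidation:
    def test_missing_taxonomy_entry_named(self):
        idx = pd.Index(["Zotu1", "Zotu2"], name="zotu")
        counts = pd.DataFrame({"s1": [1, 2]}, index=idx)
        meta = pd.DataFrame({"fraction_class": ["HF"]}, index=pd.Index(["s1"], name="sample"))
        tax = pd.DataFrame({"clade": ["A"]}, index=pd.Index(["Zotu1"], name="zotu"))
        with pytest.raises(ValueError, match="Zotu2"):
            ZotuTable(counts=counts, metadata=meta, taxonomy=tax)

    def test_negative_counts_rejected(self):
        idx = pd.Index(["Zotu1"], name="zotu")
        counts = pd.DataFrame({"s1": [-1]}, index=idx)
        meta = pd.DataFrame({"fraction_class": ["HF"]}, index=pd.Index(["s1"], name="sample"))
        tax = pd.DataFrame({"clade": ["A"]}, index=idx)
        with pytest.raises(ValueError):
            ZotuTable(counts=counts, metadata=meta, taxonomy=tax)
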