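import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import distance as sp_distance
from skbio.diversity import alpha as skbio_alpha

import amplitag as at
from amplitag.community import TraitTable


def tiny_table(counts: dict, taxonomy=None, samples=None):
    df = pd.DataFrame(counts).T
    tax = pd.DataFrame(taxonomy).T if taxonomy is not None else None
    meta = pd.DataFrame(samples).T if samples is not None else None
    if meta is not None:
        meta.index.name = "sample_id"
    return at.OtuTable(df, tax, meta)


class TestRareFilter:
    def test_exact_threshold_boundary(self):
        # grand total 20,000: 1 read = 0.005% removed, 2 reads = 0.01% kept
        counts = {"otu_rare": {"s1": 1, "s2": 0},
                  "otu_edge": {"s1": 1, "s2": 1},
                  "otu_big": {"s1": 10000, "s2": 9997}}
        filtered = at.rare_filter(tiny_table(counts))
        assert list(filtered.counts.index) == ["otu_edge", "otu_big"]

    def test_zero_threshold_is_identity(self, desk_table):
        table, _, _ = desk_table
        assert at.rare_filter(table, 0.0).counts.equals(table.counts)

    def test_all_abundant_untouched(self):
        counts = {"a": {"s1": 100}, "b": {"s1": 300}}
        assert at.rare_filter(tiny_table(counts)).n_otus == 2

    def test_commutes_with_nontarget_removal(self, desk_table):
        table, _, _ = desk_table
        a, _ = at.remove_nontarget(at.rare_filter(table))
        b = at.rare_filter(at.remove_nontarget(table)[0], pool_total=table.grand_total)
        assert sorted(a.counts.index) == sorted(b.counts.index)


class TestParseBestHits:
    def test_minimal_evalue_wins(self):
        df = pd.DataFrame(
            [["q1", "hitA", 95.0, 1e-60], ["q1", "hitB", 99.0, 1e-55]],
            columns=["query", "subject", "pident", "evalue"],
        )
        best = at.parse_best_hits(df)
        assert best.loc["q1", "subject"] == "hitA"
        assert bool(best.loc["q1", "assigned"])

    def test_evalue_gate_excludes_weak_best_hit(self):
        df = pd.DataFrame(
            [["q1", "hitA", 95.0, 1e-40]],
            columns=["query", "subject", "pident", "evalue"],
        )
        best = at.parse_best_hits(df)
        assert not bool(best.loc["q1", "assigned"])

    def test_gate_is_inclusive_at_cutoff(self):
        df = pd.DataFrame(
            [["q1", "hitA", 95.0, 1e-50]],
            columns=["query", "subject", "pident", "evalue"],
        )
        assert bool(at.parse_best_hits(df).loc["q1", "assigned"])

    def test_identity_breaks_evalue_ties(self):
        df = pd.DataFrame(
            [["q1", "hitA", 97.0, 1e-60], ["q1", "hitB", 99.0, 1e-60]],
            columns=["query", "subject", "pident", "evalue"],
        )
        assert at.parse_best_hits(df).loc["q1", "subject"] == "hitB"

    def test_malformed_rows_skipped_with_warning(self, tmp_path):
        path = tmp_path / "hits.tsv"
        good = "q1\thitA\t98.5\t350\t5\t0\t1\t350\t1\t350\t1e-120\t600"
        path.write_text(good + "\nq2\tbroken_row\n")
        with pytest.warns(UserWarning):
            best = at.parse_best_hits(path)
        assert list(best.index) == ["q1"]

    def test_taxonomy_path_splitting(self):
        ranks = at.split_taxonomy_path("Cercozoa;Sarcomonadea;Glissomonadida")
        assert ranks["phylum"] == "Cercozoa"
        assert ranks["order"] == "Glissomonadida"
        assert ranks["species"] == ""


class TestRemoveNontarget:
    def test_target_kept_fungus_removed(self):
        counts = {"o1": {"s": 5}, "o2": {"s": 5}}
        tax = {"o1": {"phylum": "Cercozoa"}, "o2": {"phylum": "Fungi"}}
        filtered, retained = at.remove_nontarget(tiny_table(counts, tax))
        assert list(filtered.counts.index) == ["o1"]
        assert retained == 0.5

    def test_endomyxa_is_a_target(self):
        counts = {"o1": {"s": 5}}
        tax = {"o1": {"phylum": "Endomyxa"}}
        filtered, retained = at.remove_nontarget(tiny_table(counts, tax))
        assert filtered.n_otus == 1 and retained == 1.0

    def test_planted_92_percent_target_fraction_recovered(self, desk_table):
        table, _, truth = desk_table
        _, retained = at.remove_nontarget(table)
        assert retained == pytest.approx(truth["n_target"] / table.n_otus)


class TestAnnotateTraits:
    def test_key_species_from_default_catalog(self):
        counts = {"o1": {"s": 5}, "o2": {"s": 5}}
        tax = {
            "o1": {"phylum": "Endomyxa", "genus": "Polymyxa",
                   "species": "Polymyxa graminis"},
            "o2": {"phylum": "Endomyxa", "genus": "Woronina",
                   "species": "Woronina pythii"},
        }
        annotated = at.annotate_traits(tiny_table(counts, tax), TraitTable.default())
        assert annotated.taxonomy.loc["o1", "nutrition"] == "plant parasite"
        assert annotated.taxonomy.loc["o2", "nutrition"] == "hyperparasite of Oomycota"
        assert annotated.taxonomy.loc["o1", "trait_rank"] == "species"

    def test_order_level_fallback(self):
        counts = {"o1": {"s": 5}}
        tax = {"o1": {"phylum": "Cercozoa", "order": "Glissomonadida",
                      "genus": "Unknowngenus"}}
        annotated = at.annotate_traits(tiny_table(counts, tax), TraitTable.default())
        assert annotated.taxonomy.loc["o1", "nutrition"] == "bacterivore"
        assert annotated.taxonomy.loc["o1", "trait_rank"] == "order"

    def test_unmatched_otu_stays_unknown(self):
        counts = {"o1": {"s": 5}}
        tax = {"o1": {"phylum": "Cercozoa", "genus": "Mysterium"}}
        annotated = at.annotate_traits(tiny_table(counts, tax), TraitTable.default())
        assert annotated.taxonomy.loc["o1", "nutrition"] == "unknown"

    def test_closed_vocabulary_enforced(self):
        bad = pd.DataFrame(
            [{"taxon": "X", "rank": "genus", "nutrition": "carnivore",
              "morphology": "naked amoeba", "locomotion": "swimming"}]
        )
        with pytest.raises(ValueError):
            TraitTable(bad)


class TestGuildRelabund:
    def test_single_guild_is_100_percent(self):
        counts = {"o1": {"s1": 5}, "o2": {"s1": 10}}
        tax = {"o1": {"nutrition": "bacterivore"}, "o2": {"nutrition": "bacterivore"}}
        g = at.guild_relabund(tiny_table(counts, tax))
        assert g.loc["bacterivore", "all"] == pytest.approx(100.0)

    def test_equal_reads_split_evenly(self):
        counts = {"o1": {"s1": 7}, "o2": {"s1": 7}}
        tax = {"o1": {"nutrition": "bacterivore"}, "o2": {"nutrition": "eukaryvore"}}
        g = at.guild_relabund(tiny_table(counts, tax))
        assert g.loc["bacterivore", "all"] == pytest.approx(50.0)
        assert g.loc["eukaryvore", "all"] == pytest.approx(50.0)

    def test_columns_sum_to_100_and_weighting_is_labelled(self, desk_table):
        table, traits, _ = desk_table
        annotated = at.annotate_traits(at.remove_nontarget(table)[0], traits)
        for weight in ("reads", "otus"):
            g = at.guild_relabund(annotated, weight=weight)
            assert np.allclose(g.sum(axis=0), 100.0, atol=1e-9)
            assert g.attrs["weight"] == weight

    def test_planted_mixture_recovered_exactly_by_otu_weighting(self, desk_table):
        table, traits, truth = desk_table
        annotated = at.annotate_traits(at.remove_nontarget(table)[0], traits)
        g = at.guild_relabund(annotated, weight="otus")["all"]
        for guild, count in truth["guild_counts"].items():
            assert g.get(guild, 0.0) == pytest.approx(100.0 * count / truth["n_target"])

    def test_percentages_invariant_under_sample_order(self, desk_table):
        table, traits, _ = desk_table
        annotated = at.annotate_traits(table, traits)
        shuffled = at.OtuTable(
            annotated.counts[annotated.counts.columns[::-1]],
            annotated.taxonomy, annotated.samples,
        )
        pd.testing.assert_frame_equal(
            at.guild_relabund(annotated), at.guild_relabund(shuffled)
        )


class TestSharingStats:
    def test_three_otu_example(self):
        counts = {"both": {"g1": 3, "f1": 2},
                  "g_only": {"g1": 4, "f1": 0},
                  "f_only": {"g1": 0, "f1": 9}}
        samples = {"g1": {"ecosystem": "G"}, "f1": {"ecosystem": "F"}}
        stats = at.sharing_stats(tiny_table(counts, samples=samples))
        assert stats["shared"] == 1
        assert stats["unique"] == {"G": 1, "F": 1}

    def test_everything_everywhere_all_shared(self):
        counts = {"a": {"g1": 1, "f1": 1}, "b": {"g1": 2, "f1": 2}}
        samples = {"g1": {"ecosystem": "G"}, "f1": {"ecosystem": "F"}}
        stats = at.sharing_stats(tiny_table(counts, samples=samples))
        assert stats["shared"] == stats["total"] == 2

    def test_planted_sharing_recovered(self, desk_table):
        table, _, truth = desk_table
        target, _ = at.remove_nontarget(table)
        stats = at.sharing_stats(target)
        assert stats["shared"] == truth["n_shared"]
        assert stats["unique"] == {"G": truth["n_g_only"], "F": truth["n_f_only"]}
        assert stats["shared"] + sum(stats["unique"].values()) <= stats["total"]


class TestDiversity:
    def test_uniform_community_closed_form(self):
        h = at.shannon([1, 1, 1, 1])
        assert h == pytest.approx(math.log(4))
        assert at.pielou(h, 4) == pytest.approx(1.0)

    def test_single_taxon(self):
        assert at.shannon([10]) == pytest.approx(0.0)
        assert at.pielou(0.0, 1) == 0.0

    def test_bray_curtis_hand_example(self):
        assert at.bray_curtis([2, 2], [2, 0]) == pytest.approx(1 / 3)

    def test_bray_curtis_undefined_for_zero_vectors(self):
        with pytest.raises(ValueError):
            at.bray_curtis([0, 0], [0, 0])

    def test_agrees_with_scipy_and_skbio(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            x = rng.integers(0, 50, size=12)
            y = rng.integers(0, 50, size=12)
            if x.sum() == 0 or y.sum() == 0 or (x + y).sum() == 0:
                continue
            assert at.bray_curtis(x, y) == pytest.approx(
                sp_distance.braycurtis(x, y)
            )
            assert at.shannon(x[x > 0]) == pytest.approx(
                float(skbio_alpha.shannon(x[x > 0], base=math.e))
            )

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=20),
        st.data(),
    )
    def test_bray_curtis_properties(self, x, data):
        y = data.draw(
            st.lists(st.integers(0, 1000), min_size=len(x), max_size=len(x))
        )
        if sum(x) + sum(y) == 0:
            return
        bc = at.bray_curtis(x, y)
        assert 0.0 <= bc <= 1.0
        assert bc == pytest.approx(at.bray_curtis(y, x))
        if sum(x) > 0:
            assert at.bray_curtis(x, x) == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(1, 1000), min_size=1, max_size=30))
    def test_shannon_bounds_and_pielou_range(self, counts):
        h = at.shannon(counts)
        s = len(counts)
        assert -1e-12 <= h <= math.log(s) + 1e-12 if s > 1 else h == 0.0
        assert 0.0 <= at.pielou(h, s) <= 1.0 + 1e-12

    def test_matrix_is_symmetric_zero_diagonal(self, desk_table):
        table, _, _ = desk_table
        sub = at.OtuTable(table.counts.iloc[:, :6], table.taxonomy, table.samples)
        m = at.bray_curtis_matrix(sub)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)

    def test_alpha_diversity_table(self, desk_table):
        table, _, _ = desk_table
        alpha = at.alpha_diversity(table)
        assert (alpha["pielou"] <= 1.0).all()
        assert (alpha["shannon"] <= np.log(alpha["richness"])).all()


class TestOtuTableIO:
    def test_round_trip(self, tmp_path, desk_table):
        table, _, _ = desk_table
        paths = [tmp_path / n for n in ("c.tsv", "t.tsv", "s.tsv")]
        table.write(*paths)
        back = at.OtuTable.read(*paths)
        pd.testing.assert_frame_equal(back.counts, table.counts)
        assert list(back.samples["ecosystem"]) == list(table.samples["ecosystem"])
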