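import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import TreeNode

from biofilm_assembly import (
    CommunityTable,
    NullModelConfig,
    ScenarioConfig,
    beta_mpd,
    bin_taxa,
    classify,
    quantify_assembly,
    simulate_scenario,
    simulate_tree,
)
from biofilm_assembly.assembly import (
    PROCESSES,
    aggregate,
    beta_nri_matrix,
    cophenetic_matrix,
    rc_bray_matrix,
    score_pairs,
)

CFG = NullModelConfig(n_null=200, bin_size_min=6, seed=0)


def _table_for(tree, counts=None, n_samples=2):
    taxa = [t.name for t in tree.tips()]
    if counts is None:
        counts = np.ones((n_samples, len(taxa)), dtype=int)
    return CommunityTable([f"S{i}" for i in range(len(counts))], taxa, counts)


class TestBinning:
    def test_large_cut_gives_single_bin(self):
        tree = simulate_tree(20, seed=1)
        table = _table_for(tree)
        cfg = NullModelConfig(ds_cut=10.0, bin_size_min=1)
        bins = bin_taxa(tree, table, cfg)
        assert len(bins) == 1 and len(bins[0]) == 20

    def test_tiny_cut_gives_one_bin_per_tip(self):
        tree = simulate_tree(12, seed=2)
        table = _table_for(tree)
        cfg = NullModelConfig(ds_cut=1e-12, bin_size_min=1)
        bins = bin_taxa(tree, table, cfg)
        assert len(bins) == 12
        assert all(len(b) == 1 for b in bins)

    def test_two_cluster_tree_recovers_clades(self):
        """Two dense 6-tip clusters on long stems: a cut between the
        cluster and stem scales yields exactly the two clades."""
        cluster = "({}:0.05,({}:0.04,({}:0.03,({}:0.02,({}:0.01,{}:0.01):0.01):0.01):0.01):0.01)"
        left = cluster.format(*[f"a{i}" for i in range(6)])
        right = cluster.format(*[f"b{i}" for i in range(6)])
        tree = TreeNode.read(io.StringIO(f"({left}:1.0,{right}:1.0);"))
        table = _table_for(tree)
        # brute-force check of the fixture's scales
        d = cophenetic_matrix(tree, table.taxon_ids)
        a_idx = [i for i, t in enumerate(table.taxon_ids) if t.startswith("a")]
        b_idx = [i for i, t in enumerate(table.taxon_ids) if t.startswith("b")]
        within = max(d[np.ix_(a_idx, a_idx)].max(), d[np.ix_(b_idx, b_idx)].max())
        across = d[np.ix_(a_idx, b_idx)].min()
        assert within < 0.5 < across
        bins = bin_taxa(tree, table, NullModelConfig(ds_cut=0.5, bin_size_min=2))
        assert len(bins) == 2
        assert {frozenset(t for t in table.taxon_ids if t.startswith("a")),
                frozenset(t for t in table.taxon_ids if t.startswith("b"))} == {
            frozenset(b.taxa) for b in bins
        }

    def test_bins_partition_taxa_and_respect_minimum(self):
        tree = simulate_tree(50, seed=3)
        table = _table_for(tree)
        cfg = NullModelConfig(bin_size_min=8)
        bins = bin_taxa(tree, table, cfg)
        all_taxa = [t for b in bins for t in b.taxa]
        assert sorted(all_taxa) == sorted(table.taxon_ids)
        assert all(len(b) >= 8 for b in bins)

    def test_min_size_above_taxon_count_rejected(self):
        tree = simulate_tree(5, seed=4)
        table = _table_for(tree)
        with pytest.raises(ValueError):
            bin_taxa(tree, table, NullModelConfig(bin_size_min=10))


class TestBetaMpd:
    def test_worked_examples(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 4.0], [2.0, 4.0, 0.0]])
        # single identical taxon in both samples
        assert beta_mpd([1, 0, 0], [5, 0, 0], d) == pytest.approx(0.0, abs=1e-12)
        # single distinct taxa → their distance
        assert beta_mpd([1, 0, 0], [0, 0, 3], d) == pytest.approx(2.0, abs=1e-12)
        # A: a=0.5, b=0.5; B: c=1.0; d(a,c)=2, d(b,c)=4 → 3.0
        assert beta_mpd([1, 1, 0], [0, 0, 7], d) == pytest.approx(3.0, abs=1e-9)

    def test_absent_bin_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            beta_mpd([0, 0], [1, 1], d)

    def test_unweighted_uses_presence_only(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        w = beta_mpd([9, 1], [1, 9], d, abundance_weighted=True)
        u = beta_mpd([9, 1], [1, 9], d, abundance_weighted=False)
        assert u == pytest.approx(0.5, abs=1e-12)
        assert w != pytest.approx(u, abs=1e-6)


class TestBetaNri:
    def test_star_subtree_null_is_degenerate(self):
        """Equidistant taxa: every shuffle preserves all distances, so the
        null has zero spread and the score falls through to RC."""
        d = np.full((4, 4), 1.5)
        np.fill_diagonal(d, 0.0)
        counts = np.array([[5, 3, 2, 1], [1, 2, 3, 5]])
        bnri, degenerate = beta_nri_matrix(counts, d, CFG, np.random.default_rng(0))
        assert degenerate[0, 1]
        assert bnri[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_seed_reproducible(self):
        tree = simulate_tree(10, seed=5)
        d = cophenetic_matrix(tree, [t.name for t in tree.tips()])
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, size=(4, 10)) + 1
        a, _ = beta_nri_matrix(counts, d, CFG, np.random.default_rng(9))
        b, _ = beta_nri_matrix(counts, d, CFG, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_absent_bin_is_nan(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        counts = np.array([[0, 0], [1, 2]])
        bnri, _ = beta_nri_matrix(counts, d, CFG, np.random.default_rng(0))
        assert np.isnan(bnri[0, 1])

    def test_doubling_n_null_is_stable(self):
        """βNRI shifts by less than 3× the null-mean standard error when
        n_null doubles on a fixed fixture."""
        tree = simulate_tree(16, seed=6)
        d = cophenetic_matrix(tree, [t.name for t in tree.tips()])
        counts = np.random.default_rng(5).integers(0, 30, size=(3, 16)) + 1
        c200 = NullModelConfig(n_null=200, bin_size_min=6, seed=0)
        c400 = NullModelConfig(n_null=400, bin_size_min=6, seed=0)
        a, _ = beta_nri_matrix(counts, d, c200, np.random.default_rng(1))
        b, _ = beta_nri_matrix(counts, d, c400, np.random.default_rng(2))
        tol = 3 * np.sqrt(1 / 200 + 1 / 400)
        assert np.nanmax(np.abs(a - b)) < tol * (1 + np.nanmax(np.abs(a)))


class TestRcBray:
    def test_identical_pair_in_patchy_set_hits_floor(self):
        """Two identical samples amid divergent ones are more similar than
        every richness/abundance-preserving null draw → RC = −1."""
        rng = np.random.default_rng(0)
        shared = rng.integers(1, 40, size=12)
        counts = np.vstack(
            [shared, shared]
            + [np.where(rng.random(12) < 0.5, 0, rng.integers(1, 40, 12)) for _ in range(4)]
        )
        rc = rc_bray_matrix(counts, CFG, np.random.default_rng(1))
        assert rc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_disjoint_pair_reaches_upper_tail(self):
        """Two samples on disjoint taxon sets are at or beyond the null's
        upper range. Null draws that also realise disjoint supports tie at
        the Bray-Curtis ceiling, so RC sits at +1 up to the tie share."""
        counts = np.array(
            [
                [30, 20, 10, 0, 0, 0],
                [0, 0, 0, 30, 20, 10],
                [10, 10, 10, 10, 10, 10],
                [5, 10, 15, 15, 10, 5],
            ]
        )
        rc = rc_bray_matrix(counts, CFG, np.random.default_rng(2))
        assert 0.95 < rc[0, 1] <= 1.0

    def test_typical_draws_sit_mid_null(self):
        """Samples that are themselves random assemblies score near 0."""
        rng = np.random.default_rng(3)
        p = np.ones(15) / 15
        counts = np.vstack([rng.multinomial(300, p) for _ in range(6)])
        rc = rc_bray_matrix(counts, CFG, np.random.default_rng(4))
        iu = np.triu_indices(6, 1)
        assert abs(np.nanmean(rc[iu])) < 0.5

    def test_absent_bin_is_nan(self):
        counts = np.array([[0, 0, 0], [1, 2, 3]])
        rc = rc_bray_matrix(counts, CFG, np.random.default_rng(0))
        assert np.isnan(rc[0, 1])


class TestClassify:
    @pytest.mark.parametrize(
        "bnri, rc, expected",
        [
            (2.5, 0.0, "HeS"),
            (-2.5, 0.0, "HoS"),
            (0.3, 0.97, "DL"),
            (0.3, -0.97, "HD"),
            (0.3, 0.0, "DR"),
            (1.96, 0.95, "DR"),  # boundary equality → stochastic side
            (-1.96, -0.95, "DR"),
        ],
    )
    def test_threshold_rules(self, bnri, rc, expected):
        assert classify(bnri, rc, CFG) == expected

    @given(
        bnri=st.floats(-50, 50, allow_nan=False),
        rc=st.floats(-1, 1, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_exhaustive_and_exclusive(self, bnri, rc):
        assert classify(bnri, rc, CFG) in PROCESSES


class TestAggregate:
    def _scores(self, rows):
        return pd.DataFrame(
            rows,
            columns=["sample_a", "sample_b", "bin_id", "process", "weight"],
        )

    def test_two_bin_weighting(self):
        sc = self._scores(
            [("A", "B", 0, "HoS", 0.7), ("A", "B", 1, "DR", 0.3)]
        )
        out = aggregate(sc)
        assert out.loc[0, "HoS"] == pytest.approx(0.7)
        assert out.loc[0, "DR"] == pytest.approx(0.3)
        assert out.loc[0, ["HeS", "HD", "DL"]].sum() == 0

    def test_single_bin_gets_everything(self):
        out = aggregate(self._scores([("A", "B", 0, "DL", 0.4)]))
        assert out.loc[0, "DL"] == pytest.approx(1.0)

    def test_group_mean_matches_hand_computation(self):
        sc = self._scores(
            [
                ("A", "B", 0, "HoS", 1.0),
                ("A", "C", 0, "HoS", 0.5),
                ("A", "C", 1, "DR", 0.5),
                ("B", "C", 0, "DR", 1.0),
            ]
        )
        out = aggregate(sc).set_index(["sample_a", "sample_b"])
        mean_hos = out["HoS"].mean()
        assert mean_hos == pytest.approx((1.0 + 0.5 + 0.0) / 3)

    def test_fractions_always_sum_to_one(self):
        study = simulate_scenario(ScenarioConfig("DR", n_taxa=40, n_samples=5, depth=300, seed=8))
        cfg = NullModelConfig(n_null=100, bin_size_min=4, seed=1)
        res = quantify_assembly(study.table, study.tree, None, None, cfg)
        np.testing.assert_allclose(
            res.pair_fractions[list(PROCESSES)].sum(axis=1), 1.0, atol=1e-9
        )
        np.testing.assert_allclose(
            res.group_fractions[list(PROCESSES)].sum(axis=1), 1.0, atol=1e-9
        )


class TestQuantifyAssembly:
    def test_identical_samples_show_no_heterogeneous_signal(self):
        """Six copies of one community can never look more dissimilar than
        the null: heterogeneous selection and dispersal limitation are 0."""
        rng = np.random.default_rng(1)
        tree = simulate_tree(30, seed=2)
        taxa = [t.name for t in tree.tips()]
        row = rng.multinomial(500, np.ones(30) / 30)
        table = CommunityTable(
            [f"S{i}" for i in range(6)], taxa, np.tile(row, (6, 1))
        )
        cfg = NullModelConfig(n_null=100, bin_size_min=4, seed=3)
        res = quantify_assembly(table, tree, None, None, cfg)
        fr = res.group_fractions.iloc[0]
        assert fr["HeS"] == pytest.approx(0.0, abs=1e-12)
        assert fr["DL"] == pytest.approx(0.0, abs=1e-12)

    def test_scores_invariant_to_taxon_column_order(self):
        study = simulate_scenario(ScenarioConfig("HoS", n_taxa=40, n_samples=5, depth=300, seed=3))
        cfg = NullModelConfig(n_null=100, bin_size_min=4, seed=7)
        r1 = quantify_assembly(study.table, study.tree, None, None, cfg)
        perm = np.random.default_rng(0).permutation(40)
        shuffled = CommunityTable(
            list(study.table.sample_ids),
            [study.table.taxon_ids[i] for i in perm],
            study.table.counts[:, perm],
        )
        r2 = quantify_assembly(shuffled, study.tree, None, None, cfg)
        key = ["sample_a", "sample_b", "bin_id"]
        s1 = r1.pair_bin_scores.sort_values(key).reset_index(drop=True)
        s2 = r2.pair_bin_scores.sort_values(key).reset_index(drop=True)
        np.testing.assert_allclose(s1["bnri"], s2["bnri"], atol=1e-12)
        np.testing.assert_allclose(s1["rc"], s2["rc"], atol=1e-12)

    def test_grouping_skips_singletons(self):
        study = simulate_scenario(ScenarioConfig("DR", n_taxa=30, n_samples=5, depth=200, seed=4))
        meta = study.metadata.copy()
        meta.loc[meta.index[-1], "day"] = 30  # one-sample group
        cfg = NullModelConfig(n_null=50, bin_size_min=4, seed=5)
        res = quantify_assembly(study.table, study.tree, meta, ["day"], cfg)
        assert list(res.group_fractions.index) == ["1"]
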