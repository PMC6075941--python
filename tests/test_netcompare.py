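"""Module matching, preservation statistics and membership comparison."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from conet import netbuild as nb
from conet import netcompare as nc

from conftest import make_expr


def hypergeom_tail_oracle(overlap, universe, n_ref, n_test):
    """P(X >= overlap) by direct enumeration of all overlap outcomes."""
    total = comb(universe, n_test)
    return sum(comb(n_ref, j) * comb(universe - n_ref, n_test - j)
               for j in range(overlap, min(n_ref, n_test) + 1)) / total


class TestHypergeomOverlap:
    def test_complete_overlap_closed_form(self):
        ref = set(range(5))
        ov, p = nc.hypergeom_overlap(ref, ref, 20)
        assert ov == 5
        assert p == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_zero_overlap_upper_tail_is_one(self):
        _, p = nc.hypergeom_overlap({1, 2}, {3, 4}, 10_000)
        assert p == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("universe,n_ref,n_test", [
        (20, 5, 5), (30, 10, 7), (25, 12, 12), (8, 3, 5),
    ])
    def test_matches_enumeration_oracle(self, universe, n_ref, n_test):
        ref = set(range(n_ref))
        rng = np.random.default_rng(universe + n_ref + n_test)
        test = set(rng.choice(universe, size=n_test, replace=False).tolist())
        ov, p = nc.hypergeom_overlap(ref, test, universe)
        assert p == pytest.approx(
            hypergeom_tail_oracle(ov, universe, n_ref, n_test), rel=1e-9)

    def test_universe_must_cover_union(self):
        with pytest.raises(ValueError):
            nc.hypergeom_overlap(set(range(10)), set(range(5, 15)), 12)


class TestOverlapPercent:
    def test_lower_bound_phrasing(self):
        # 148 of 204 genes: 72.5% -> "over 72%"
        res = nc.overlap_percent(148, 204)
        assert res.percent == pytest.approx(72.549, abs=0.01)
        assert res.floored == 72

    def test_plain_rounding(self):
        # 26 of 529 genes: 4.9% -> "only 5%"
        res = nc.overlap_percent(26, 529)
        assert res.percent == pytest.approx(4.915, abs=0.01)
        assert res.rounded == 5

    def test_zero_overlap(self):
        assert nc.overlap_percent(0, 10).percent == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nc.overlap_percent(5, 0)
        with pytest.raises(ValueError):
            nc.overlap_percent(11, 10)


class TestMatchModules:
    def make_partition(self, labels):
        return pd.Series(labels,
                         index=[f"g{i}" for i in range(len(labels))])

    def test_identical_partitions_identity_mapping(self):
        part = self.make_partition(["blue"] * 40 + ["brown"] * 40
                                   + ["grey"] * 20)
        table = nc.match_modules(part, part)
        assert table.relabeling == {"blue": "blue", "brown": "brown"}
        assert table.emergent == [] and table.lost == []
        # column sums over ref modules (incl grey row) equal test sizes
        assert (table.counts.sum(axis=0)
                == part.value_counts().reindex(table.counts.columns)).all()

    def test_scattered_reference_module_is_lost(self):
        ref = self.make_partition(["blue"] * 40 + ["brown"] * 40
                                  + ["pink"] * 20)
        # pink genes scattered uniformly across the test modules
        test = self.make_partition(["blue"] * 40 + ["brown"] * 40
                                   + ["blue", "brown"] * 10)
        table = nc.match_modules(ref, test)
        assert "pink" in table.lost
        assert table.emergent == []

    def test_split_module_spawns_emergent_matched_to_parent(self):
        ref = self.make_partition(["blue"] * 60 + ["brown"] * 40)
        test = self.make_partition(["m1"] * 40 + ["m2"] * 20
                                   + ["m3"] * 40)
        table = nc.match_modules(ref, test)
        assert table.relabeling["m1"] == "blue"
        assert table.relabeling["m3"] == "brown"
        # the smaller half of blue gets a fresh color but best-matches blue
        assert table.emergent == ["m2"]
        assert table.best_match["m2"] == "blue"
        assert table.relabeling["m2"] not in {"blue", "brown", "grey"}

    def test_disjoint_universes_rejected(self):
        a = self.make_partition(["blue"] * 10)
        b = pd.Series(["blue"] * 10, index=[f"x{i}" for i in range(10)])
        with pytest.raises(ValueError):
            nc.match_modules(a, b)


@pytest.fixture(scope="module")
def two_condition_data():
    """150 genes: one preserved module, one disrupted module, background.

    In condition B the second module's genes are re-randomized, destroying
    its coexpression while the first module is untouched. Loadings are
    spread so modules have internal hub structure (without it the
    connectivity statistics have no variation to reproduce)."""
    rng = np.random.default_rng(21)
    n, msize, nbg = 100, 30, 90
    f1a, f2a = rng.standard_normal((2, n))
    f1b = rng.standard_normal(n)
    lam1 = rng.uniform(0.4, 0.95, size=(msize, 1))
    lam2 = rng.uniform(0.4, 0.95, size=(msize, 1))
    va = np.vstack([
        lam1 * f1a + 0.25 * rng.standard_normal((msize, n)),
        lam2 * f2a + 0.25 * rng.standard_normal((msize, n)),
        rng.standard_normal((nbg, n)),
    ])
    vb = np.vstack([
        lam1 * f1b + 0.25 * rng.standard_normal((msize, n)),
        rng.standard_normal((msize, n)),       # module 2 destroyed
        rng.standard_normal((nbg, n)),
    ])
    genes = [f"g{i}" for i in range(2 * msize + nbg)]
    ref = make_expr(va, gene_ids=genes)
    test = make_expr(vb, gene_ids=genes)
    partition = pd.Series(["blue"] * msize + ["brown"] * msize
                          + ["grey"] * nbg, index=genes)
    return ref, test, partition


class TestModulePreservation:
    def test_preserved_high_disrupted_low(self, two_condition_data):
        ref, test, partition = two_condition_data
        rep = nc.module_preservation(ref, test, partition, power=6,
                                     n_perm=100, seed=0)
        z = rep.summary["Zsummary"]
        assert z["blue"] > 10       # untouched module: strong evidence
        assert z["brown"] < 2       # destroyed module: none
        assert (rep.summary.loc["brown", "medianRank"]
                > rep.summary.loc["blue", "medianRank"])

    def test_observed_stats_invariant_to_gene_and_sample_order(
            self, two_condition_data):
        ref, test, partition = two_condition_data
        rep = nc.module_preservation(ref, test, partition, power=6,
                                     n_perm=25, seed=0)
        rng = np.random.default_rng(4)
        gene_perm = list(rng.permutation(ref.features))
        sample_perm = list(rng.permutation(test.samples))
        ref2 = ref.subset_features(gene_perm)
        test2 = test.subset_features(gene_perm).subset_samples(sample_perm)
        rep2 = nc.module_preservation(ref2, test2, partition, power=6,
                                      n_perm=25, seed=0)
        pd.testing.assert_frame_equal(
            rep.observed.sort_index(), rep2.observed.sort_index(),
            atol=1e-10, rtol=0)

    def test_random_sets_z_centered_near_zero(self, two_condition_data):
        ref, test, partition = two_condition_data
        rng = np.random.default_rng(17)
        extra = {f"rand{i}": list(rng.choice(ref.features, size=15,
                                             replace=False))
                 for i in range(50)}
        empty = pd.Series(["grey"] * len(ref.features), index=ref.features)
        rep = nc.module_preservation(ref, test, empty, power=6, n_perm=500,
                                     seed=2, extra_sets=extra)
        z = rep.summary.loc[list(extra), "Zsummary"]
        assert abs(z.mean()) < 0.3

    def test_small_modules_skipped(self, two_condition_data):
        ref, test, _ = two_condition_data
        n = len(ref.features)
        partition = pd.Series(["tiny"] * 2 + ["blue"] * 38
                              + ["grey"] * (n - 40), index=ref.features)
        rep = nc.module_preservation(ref, test, partition, power=6,
                                     n_perm=25, seed=0)
        assert "tiny" in rep.skipped
        assert "tiny" not in rep.summary.index

    def test_low_permutation_count_warns(self, two_condition_data):
        ref, test, partition = two_condition_data
        with pytest.warns(UserWarning, match="n_perm"):
            nc.module_preservation(ref, test, partition, power=6,
                                   n_perm=10, seed=0)


class TestMMCorrelation:
    def test_identical_networks_give_unit_correlation(self, planted,
                                                      planted_networks):
        net = planted_networks["WT"]
        mm = nc.mm_correlation(net["kme"], net["kme"], net["partition"])
        assert np.allclose(mm["cor_all"].dropna(), 1.0)
        assert np.allclose(mm["cor_module"].dropna(), 1.0)

    def test_tiny_module_reported_as_nan(self):
        kme = pd.DataFrame({"m1": [0.9, 0.8, 0.7, 0.6]},
                           index=list("abcd"))
        part = pd.Series(["m1", "m1", "grey", "grey"], index=list("abcd"))
        mm = nc.mm_correlation(kme, kme, part)
        assert np.isnan(mm.loc["m1", "cor_module"])
        assert mm.loc["m1", "n_module_genes"] == 2

    def test_module_missing_in_test_network_reported_absent(self):
        ref_kme = pd.DataFrame({"m1": [0.9, 0.8], "m2": [0.1, 0.2]},
                               index=["a", "b"])
        test_kme = pd.DataFrame({"m1": [0.9, 0.8]}, index=["a", "b"])
        part = pd.Series(["m1", "m2"], index=["a", "b"])
        mm = nc.mm_correlation(ref_kme, test_kme, part)
        assert np.isnan(mm.loc["m2", "cor_all"])
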