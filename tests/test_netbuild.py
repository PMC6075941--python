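"""Network construction: bicor, adjacency, TOM, soft threshold, module
detection, eigengenes, module membership, hubs and edge export."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conet import netbuild as nb
from conet.expr import ExpressionMatrix
from conet.simulate import SyntheticSpec, generate

from conftest import make_expr


def bicor_oracle(x, y):
    """Straight-line biweight midcorrelation, independent of the library
    implementation: median-centered, Tukey-biweight-weighted deviations."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    xt, yt = transform(x), transform(y)
    return np.sum(xt * yt) / np.sqrt(np.sum(xt ** 2) * np.sum(yt ** 2))


class TestBicor:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        assert nb.bicor(x, x) == pytest.approx(1.0)
        assert nb.bicor(x, -x) == pytest.approx(-1.0)

    def test_outlier_downweighted_vs_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = nb.bicor(x, y)
        assert b == pytest.approx(bicor_oracle(x, y), abs=1e-12)
        pearson = np.corrcoef(x, y)[0, 1]
        assert abs(b - pearson) > 0.05

    def test_reduces_to_pearson_without_outliers(self):
        # symmetric data tight around the median: all weights equal is not
        # attainable (weights vary smoothly), so compare on a vector whose
        # weighted and unweighted answers coincide by symmetry
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, 50)
        y = 2.0 * x  # exact linear relation survives any symmetric weighting
        assert nb.bicor(x, y) == pytest.approx(1.0, abs=1e-12)
        assert nb.bicor(x, -y) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_vector_flagged_zero(self):
        x = np.ones(6)
        y = np.arange(6.0)
        with pytest.warns(UserWarning, match="constant"):
            assert nb.bicor(x, y) == 0.0

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            nb.bicor([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestCorrelationMatrix:
    def test_collinear_genes_fully_correlated(self):
        base = np.array([1.0, 2.0, 5.0, 3.0, 4.0, 6.0])
        m = make_expr(np.vstack([base, 2 * base + 1, 0.5 * base - 2]))
        r = nb.correlation_matrix(m).to_numpy()
        assert np.allclose(r, 1.0)

    def test_independent_genes_near_zero(self):
        rng = np.random.default_rng(0)
        m = make_expr(rng.standard_normal((40, 1000)))
        r = nb.correlation_matrix(m).to_numpy()
        iu = np.triu_indices(40, 1)
        assert np.abs(r[iu]).mean() < 0.05

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((10, 6))
        m = make_expr(vals)
        r = nb.correlation_matrix(m).to_numpy()
        for i in range(10):
            for j in range(i + 1, 10):
                assert r[i, j] == pytest.approx(
                    bicor_oracle(vals[i], vals[j]), abs=1e-10)
        assert np.allclose(r, r.T, atol=1e-10)
        assert np.allclose(np.diag(r), 1.0)


class TestAdjacency:
    def test_signed_endpoints_and_closed_form(self):
        corr = pd.DataFrame([[1.0, 1.0, -1.0, 0.0],
                             [1.0, 1.0, 0.5, 0.0],
                             [-1.0, 0.5, 1.0, 0.0],
                             [0.0, 0.0, 0.0, 1.0]])
        a = nb.adjacency(corr, 6).to_numpy()
        assert a[0, 1] == pytest.approx(1.0)       # r=1 -> 1 for any power
        assert a[0, 2] == pytest.approx(0.0)       # r=-1 -> 0 (signed)
        assert a[0, 3] == pytest.approx(0.5 ** 6)  # r=0 -> 0.015625

    def test_monotone_in_correlation(self):
        r = np.linspace(-1, 1, 21)
        corr = pd.DataFrame(np.diag(np.ones(21)))
        for beta in (1, 4, 9):
            a = ((1 + r) / 2) ** beta
            assert (np.diff(a) >= 0).all()

    def test_power_below_one_rejected(self):
        with pytest.raises(ValueError):
            nb.adjacency(pd.DataFrame(np.eye(3)), 0.5)


def tom_oracle(a):
    """Triple-loop topological overlap, independent of the matrix algebra."""
    a = np.asarray(a, float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n)
                         if u not in (i, j))
            t[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


class TestTOM:
    def test_identical_neighborhoods_give_unit_overlap(self):
        # two fully linked genes sharing every neighbor at full weight
        a = np.ones((5, 5))
        tom = nb.tom_similarity(pd.DataFrame(a)).to_numpy()
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            a = rng.uniform(0, 1, size=(4, 4))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = nb.tom_similarity(pd.DataFrame(a)).to_numpy()
            assert np.allclose(tom, tom_oracle(a), atol=1e-12)

    def test_bounded_on_random_adjacency(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 1, size=(20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = nb.tom_similarity(pd.DataFrame(a)).to_numpy()
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            nb.tom_similarity(pd.DataFrame(a))


class TestSoftThreshold:
    def test_perfect_correlation_degenerate(self):
        corr = pd.DataFrame(np.ones((10, 10)))
        with pytest.raises(ValueError, match="degenerate|identical"):
            nb.pick_soft_threshold(corr)

    def test_mean_connectivity_decreases_with_power(self, planted):
        matrices, _ = planted
        corr = nb.correlation_matrix(matrices["WT"])
        _, table = nb.pick_soft_threshold(corr, n_samples=60)
        assert (np.diff(table["mean_k"]) < 0).all()

    def test_candidates_must_be_ascending(self):
        corr = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError):
            nb.pick_soft_threshold(corr, candidate_powers=[6, 2])


class TestDetectModules:
    def test_recovers_planted_modules(self):
        # fixed loading 0.7, noise 0.5: the module-recovery stress case
        spec = SyntheticSpec(n_genes=500, module_sizes=(100,) * 5,
                             n_samples_per_stratum=15,
                             loading_range=(0.7, 0.7), noise_sd=0.5,
                             split_module=None, hub_shift=None,
                             de_config=(), marker_config={},
                             nb_dispersion=None, seed=8)
        mats, truth = generate(spec)
        m = mats["WT"]
        corr = nb.correlation_matrix(m)
        power, _ = nb.pick_soft_threshold(corr, n_samples=m.n_samples)
        diss = 1.0 - nb.tom_similarity(nb.adjacency(corr, power))
        cfg = nb.NetworkConfig(power=power)
        partition, _ = nb.detect_modules(diss, cfg, expr=m)
        ari = adjusted_rand_score(truth.module_labels["WT"].values,
                                  partition.values)
        assert ari >= 0.9

    def test_noise_stays_unassigned_with_conservative_split(self, noise_diss):
        cfg = nb.NetworkConfig(power=6, deep_split=0)
        partition, _ = nb.detect_modules(noise_diss, cfg)
        assert (partition == nb.GREY).mean() >= 0.8

    def test_highly_correlated_modules_merge(self):
        # two 60-gene blocks driven by factors correlated at 0.95: their
        # eigengene dissimilarity is ~0.05 < merge_height, so they merge
        rng = np.random.default_rng(3)
        n = 80
        f1 = rng.standard_normal(n)
        f2 = 0.95 * f1 + np.sqrt(1 - 0.95 ** 2) * rng.standard_normal(n)
        vals = np.vstack([
            0.9 * f1 + 0.1 * rng.standard_normal((60, n)),
            0.9 * f2 + 0.1 * rng.standard_normal((60, n)),
        ])
        m = make_expr(vals)
        corr = nb.correlation_matrix(m)
        diss = 1.0 - nb.tom_similarity(nb.adjacency(corr, 6))
        merged, _ = nb.detect_modules(
            diss, nb.NetworkConfig(power=6, merge_height=0.25), expr=m)
        unmerged, _ = nb.detect_modules(
            diss, nb.NetworkConfig(power=6, merge_height=None), expr=m)
        assert len(set(merged) - {nb.GREY}) == 1
        assert len(set(unmerged) - {nb.GREY}) == 2

    def test_min_module_size_larger_than_genes_rejected(self, noise_diss):
        cfg = nb.NetworkConfig(power=6, min_module_size=10_000)
        with pytest.raises(ValueError):
            nb.detect_modules(noise_diss, cfg)

    def test_largest_module_is_turquoise(self, planted_networks):
        part = planted_networks["KO"]["partition"]
        sizes = part[part != nb.GREY].value_counts()
        assert sizes["turquoise"] == sizes.max()
        # the split module's smaller half is well below the largest
        assert sizes.min() < sizes.max()


class TestEigengenes:
    def test_identical_genes_explain_all_variance(self):
        base = np.array([1.0, 4.0, 2.0, 6.0, 3.0, 5.0])
        m = make_expr(np.vstack([base, base]))
        part = pd.Series(["m1", "m1"], index=m.features)
        es = nb.eigengenes(m, part)
        assert es.prop_var_explained["m1"] == pytest.approx(1.0)
        z = (base - base.mean()) / base.std()
        cor = np.corrcoef(es.eigengenes["m1"], z)[0, 1]
        assert cor == pytest.approx(1.0)

    def test_antiphase_genes_sign_aligned(self):
        base = np.array([1.0, 4.0, 2.0, 6.0, 3.0, 5.0])
        m = make_expr(np.vstack([base, -base]))
        part = pd.Series(["m1", "m1"], index=m.features)
        es = nb.eigengenes(m, part)
        assert es.prop_var_explained["m1"] == pytest.approx(1.0)
        # deterministic sign: repeated runs agree
        es2 = nb.eigengenes(m, part)
        assert np.allclose(es.eigengenes, es2.eigengenes)

    def test_recovers_planted_factor(self):
        rng = np.random.default_rng(0)
        n = 100
        factor = rng.standard_normal(n)
        vals = 0.8 * factor + 0.3 * rng.standard_normal((20, n))
        m = make_expr(vals)
        part = pd.Series(["m1"] * 20, index=m.features)
        es = nb.eigengenes(m, part)
        cor = abs(np.corrcoef(es.eigengenes["m1"], factor)[0, 1])
        assert cor >= 0.95

    def test_unit_norm_convention(self, planted_networks):
        eg = planted_networks["WT"]["eigengenes"].eigengenes
        norms = np.linalg.norm(eg.to_numpy(), axis=0)
        assert np.allclose(norms, 1.0)


class TestModuleMembership:
    def test_kme_bounded(self, planted_networks):
        kme = planted_networks["WT"]["kme"]
        assert kme.to_numpy().min() >= -1.0
        assert kme.to_numpy().max() <= 1.0

    def test_top_loading_gene_peaks_in_own_module(self, planted,
                                                  planted_networks):
        matrices, truth = planted
        net = planted_networks["WT"]
        part, kme = net["partition"], net["kme"]
        # the designated hub of the hub-shift module carries loading 0.95
        hub = truth.hub_genes["WT"]["M2"]
        own = part[hub]
        assert kme.loc[hub].idxmax() == own


class TestTopHubs:
    def test_ranked_by_kme_with_lexicographic_ties(self):
        kme = pd.DataFrame({"m1": [0.9, 0.8, 0.9]},
                           index=["gb", "gc", "ga"])
        part = pd.Series(["m1"] * 3, index=["gb", "gc", "ga"])
        hubs = nb.top_hubs(kme, part, n=3)
        assert hubs["m1"] == ["ga", "gb", "gc"]

    def test_n_exceeding_module_returns_all(self):
        kme = pd.DataFrame({"m1": [0.9, 0.8]}, index=["ga", "gb"])
        part = pd.Series(["m1", "m1"], index=["ga", "gb"])
        assert nb.top_hubs(kme, part, n=10)["m1"] == ["ga", "gb"]

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            nb.top_hubs(pd.DataFrame(), pd.Series(dtype=object), n=0)


class TestExportEdges:
    def test_single_pair_above_threshold(self):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.6
        corr = pd.DataFrame(r, index=list("abc"), columns=list("abc"))
        part = pd.Series(["m1", "m1", "grey"], index=list("abc"))
        edges = nb.export_edges(corr, part)
        assert len(edges) == 1
        assert edges.iloc[0]["gene1"] == "a" and edges.iloc[0]["gene2"] == "b"

    def test_threshold_is_strict(self):
        r = np.eye(2)
        r[0, 1] = r[1, 0] = 0.5
        corr = pd.DataFrame(r, index=["a", "b"], columns=["a", "b"])
        part = pd.Series(["m1", "m1"], index=["a", "b"])
        assert len(nb.export_edges(corr, part, threshold=0.5)) == 0

    def test_count_matches_bruteforce(self):
        rng = np.random.default_rng(13)
        r = rng.uniform(-1, 1, size=(30, 30))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        genes = [f"g{i}" for i in range(30)]
        corr = pd.DataFrame(r, index=genes, columns=genes)
        part = pd.Series(["m1"] * 30, index=genes)
        edges = nb.export_edges(corr, part, threshold=0.3)
        expected = sum(1 for i in range(30) for j in range(i + 1, 30)
                       if r[i, j] > 0.3)
        assert len(edges) == expected

    def test_sif_roundtrip(self, tmp_path):
        corr = pd.DataFrame([[1.0, 0.7], [0.7, 1.0]],
                            index=["a", "b"], columns=["a", "b"])
        part = pd.Series(["m1", "m1"], index=["a", "b"])
        edges = nb.export_edges(corr, part)
        nb.write_sif(edges, tmp_path / "net.sif")
        assert (tmp_path / "net.sif").read_text() == "a\tcoexp\tb\n"
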