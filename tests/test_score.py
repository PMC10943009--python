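"""Signal model, SG/SSR, meta-gene matrix, re-clustering and ARI."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import modfish as mf
from tests.conftest import make_views


@pytest.fixture
def two_cluster_views():
    # cluster "t": gA mean 2, gB mean 24; cluster "u": gA mean 40, gB mean 1
    cell_scaled = np.array(
        [[2.0, 2.0, 2.0, 40.0, 40.0],
         [24.0, 24.0, 24.0, 1.0, 1.0],
         [10.0, 10.0, 10.0, 10.0, 10.0]]
    )
    labels = np.array(["t", "t", "t", "u", "u"], dtype=object)
    return make_views(cell_scaled, gene_ids=["gA", "gB", "gC"], labels=labels)


def _module(genes, probes=None, refs=(), target=None):
    return mf.PanelModule(
        "M", list(genes), probes_per_gene=probes or {},
        reference_genes=list(refs), target_label=target,
    )


class TestSignals:
    def test_gene_signal_is_probes_times_mean(self, two_cluster_views):
        assert mf.gene_signal(two_cluster_views, "gA", "t", k=24) == pytest.approx(48.0)
        assert mf.gene_signal(two_cluster_views, "gA", "t", k=1) == pytest.approx(2.0)

    def test_gene_signal_brute_force(self, rng):
        m = rng.uniform(0, 50, size=(6, 40))
        labels = rng.choice(["x", "y"], 40)
        views = make_views(m, labels=labels)
        got = mf.gene_signal(views, "g3", "y", k=7)
        expect = 7 * np.mean([m[3, i] for i in range(40) if labels[i] == "y"])
        assert got == pytest.approx(expect, rel=1e-12)

    def test_panel_signal_sums_and_commutes(self, two_cluster_views):
        mod = _module(["gA", "gB"], probes={"gA": 24, "gB": 1})
        sig = mf.panel_signal(two_cluster_views, mod, "t")
        assert sig == pytest.approx(48.0 + 24.0)
        mod_rev = _module(["gB", "gA"], probes={"gA": 24, "gB": 1})
        assert mf.panel_signal(two_cluster_views, mod_rev, "t") == pytest.approx(sig)

    def test_empty_cluster_rejected(self, two_cluster_views):
        with pytest.raises(ValueError, match="empty cluster"):
            mf.gene_signal(two_cluster_views, "gA", "missing")


class TestSignalGain:
    def test_reference_only_module_is_one(self, two_cluster_views):
        mod = _module(["gA"], refs=["gA"])
        assert mf.signal_gain(two_cluster_views, mod, "t", "general") == pytest.approx(1.0)

    def test_hand_values(self, two_cluster_views):
        # signals in t: gA(k=24) = 48, gB(k=1) = 24 -> panel 72
        mod = _module(["gA", "gB"], probes={"gA": 24}, refs=["gA"])
        assert mf.signal_gain(two_cluster_views, mod, "t", "general") == pytest.approx(1.5)
        assert mf.signal_gain(two_cluster_views, mod, "t", "conservative") == pytest.approx(1.5)
        mod_b = _module(["gA", "gB"], probes={"gA": 24}, refs=["gB"])
        assert mf.signal_gain(two_cluster_views, mod_b, "t", "general") == pytest.approx(3.0)

    def test_conservative_le_general_when_ref_is_max(self, two_cluster_views):
        mod = _module(["gA", "gB"], probes={"gA": 24}, refs=["gA"])
        sg_c = mf.signal_gain(two_cluster_views, mod, "t", "conservative")
        sg_g = mf.signal_gain(two_cluster_views, mod, "t", "general")
        assert sg_c <= sg_g + 1e-12

    def test_zero_baseline_rejected(self):
        views = make_views([[0.0, 0.0], [1.0, 1.0]], labels=["t", "u"])
        with pytest.raises(ZeroDivisionError):
            mf.signal_gain(views, _module(["g0"], refs=["g0"]), "t", "general")


class TestSSR:
    def test_hand_values_and_off_target(self):
        # target signal 80; off-targets 20 and 10
        cs = np.array([[80.0, 20.0, 10.0]])
        views = make_views(cs, gene_ids=["gA"], labels=["t", "u", "v"])
        ssr, off = mf.signal_specificity_ratio(views, _module(["gA"]), "t", "conservative")
        assert ssr == pytest.approx(4.0) and off == "u"
        ssr_g, _ = mf.signal_specificity_ratio(views, _module(["gA"]), "t", "general")
        assert ssr_g == pytest.approx(80.0 / 30.0)

    def test_target_only_expression_is_inf(self):
        views = make_views([[5.0, 0.0]], gene_ids=["gA"], labels=["t", "u"])
        ssr, _ = mf.signal_specificity_ratio(views, _module(["gA"]), "t")
        assert np.isinf(ssr)

    def test_unity_at_indistinguishability(self):
        views = make_views([[7.0, 7.0]], gene_ids=["gA"], labels=["t", "u"])
        ssr, _ = mf.signal_specificity_ratio(views, _module(["gA"]), "t")
        assert ssr == pytest.approx(1.0)

    def test_conservative_ge_general(self, rng):
        m = rng.uniform(1, 50, (4, 60))
        labels = rng.choice(["a", "b", "c"], 60)
        views = make_views(m, labels=labels)
        mod = _module(["g0", "g1"])
        c, _ = mf.signal_specificity_ratio(views, mod, "a", "conservative")
        g, _ = mf.signal_specificity_ratio(views, mod, "a", "general")
        assert c >= g

    def test_single_cluster_rejected(self):
        views = make_views([[1.0, 2.0]], gene_ids=["gA"], labels=["t", "t"])
        with pytest.raises(ValueError, match="2 clusters"):
            mf.signal_specificity_ratio(views, _module(["gA"]), "t")


class TestScaleEquivariance:
    def test_probe_scaling(self, two_cluster_views):
        mod1 = _module(["gA", "gB"], probes={"gA": 2, "gB": 3}, refs=["gA"])
        mod3 = _module(["gA", "gB"], probes={"gA": 6, "gB": 9}, refs=["gA"])
        s1 = mf.panel_signal(two_cluster_views, mod1, "t")
        s3 = mf.panel_signal(two_cluster_views, mod3, "t")
        assert s3 == pytest.approx(3 * s1)
        for mode in ("general", "conservative"):
            assert mf.signal_gain(two_cluster_views, mod1, "t", mode) == pytest.approx(
                mf.signal_gain(two_cluster_views, mod3, "t", mode)
            )
        assert mf.signal_specificity_ratio(two_cluster_views, mod1, "t")[0] == pytest.approx(
            mf.signal_specificity_ratio(two_cluster_views, mod3, "t")[0]
        )


class TestModuleCellMatrix:
    def test_singleton_module_is_gene_row(self, two_cluster_views):
        panel = mf.GenePanel([mf.PanelModule("M", ["gB"])])
        mcm = mf.module_cell_matrix(two_cluster_views, panel)
        np.testing.assert_allclose(mcm.loc["M"], two_cluster_views.cell_scaled[1])

    def test_disjoint_cover_conserves_depth(self, small_views):
        genes = list(small_views.gene_ids)
        panel = mf.GenePanel([
            mf.PanelModule("M1", genes[:25]), mf.PanelModule("M2", genes[25:]),
        ])
        mcm = mf.module_cell_matrix(small_views, panel)
        np.testing.assert_allclose(
            mcm.sum(axis=0), small_views.scale_factor, rtol=1e-9
        )

    def test_brute_force(self, rng, small_views):
        genes = list(rng.choice(small_views.gene_ids, 7, replace=False))
        panel = mf.GenePanel([mf.PanelModule("M", genes)])
        mcm = mf.module_cell_matrix(small_views, panel)
        idx = small_views.gene_index(genes)
        for c in range(0, 120, 17):
            expect = sum(small_views.cell_scaled[i, c] for i in idx)
            assert mcm.iloc[0, c] == pytest.approx(expect, rel=1e-12)

    def test_missing_gene_listed(self, small_views):
        panel = mf.GenePanel([mf.PanelModule("M", ["gene0000", "absent1"])])
        with pytest.raises(KeyError, match="absent1"):
            mf.module_cell_matrix(small_views, panel)


class TestSimulateClustering:
    def _separated_matrix(self, n_per=40):
        rng = np.random.default_rng(5)
        a = np.r_[rng.normal(100, 2, (n_per, 1)), rng.normal(5, 2, (n_per, 1))]
        b = np.r_[rng.normal(5, 2, (n_per, 1)), rng.normal(100, 2, (n_per, 1))]
        return pd.DataFrame(
            np.c_[a, b].T, index=["M1", "M2"],
            columns=[f"c{i}" for i in range(2 * n_per)],
        )

    def test_planted_types_recovered(self):
        mcm = self._separated_matrix()
        labels = mf.simulate_clustering(mcm, n_pcs=2, n_neighbors=10,
                                        resolution=0.3, seed=0)
        truth = ["a"] * 40 + ["b"] * 40
        assert mf.adjusted_rand_index(labels, truth) == pytest.approx(1.0)

    def test_resolution_zero_limit_single_cluster(self):
        # connected kNN graph (one blob): vanishing resolution merges everything
        rng = np.random.default_rng(2)
        mcm = pd.DataFrame(rng.normal(10, 1, (3, 60)), index=["M1", "M2", "M3"])
        labels = mf.simulate_clustering(mcm, n_pcs=3, n_neighbors=10,
                                        resolution=1e-4, seed=0)
        assert len(np.unique(labels)) == 1

    def test_npcs_clipped_with_warning(self):
        mcm = self._separated_matrix()
        with pytest.warns(UserWarning, match="clipped"):
            mf.simulate_clustering(mcm, n_pcs=10, n_neighbors=10, seed=0)

    def test_deterministic(self):
        mcm = self._separated_matrix()
        l1 = mf.simulate_clustering(mcm, n_pcs=2, n_neighbors=10, seed=9)
        l2 = mf.simulate_clustering(mcm, n_pcs=2, n_neighbors=10, seed=9)
        assert np.array_equal(l1, l2)

    def test_louvain_branch(self):
        mcm = self._separated_matrix()
        labels = mf.simulate_clustering(mcm, n_pcs=2, n_neighbors=10,
                                        resolution=0.3, seed=0,
                                        algorithm="louvain")
        truth = ["a"] * 40 + ["b"] * 40
        assert mf.adjusted_rand_index(labels, truth) == pytest.approx(1.0)


def _pair_counting_ari(a, b):
    """Independent ARI oracle by direct enumeration of item pairs."""
    n = len(a)
    together_a = together_b = together_both = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        together_a += sa
        together_b += sb
        together_both += sa and sb
    total = n * (n - 1) // 2
    expected = together_a * together_b / total
    max_index = (together_a + together_b) / 2
    if max_index == expected:
        return 1.0
    return (together_both - expected) / (max_index - expected)


class TestAdjustedRandIndex:
    def test_identity_and_relabelling(self):
        assert mf.adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert mf.adjusted_rand_index([1, 1, 2, 2], ["x", "x", "y", "y"]) == 1.0

    def test_hand_value(self):
        assert mf.adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_exhaustive_small_labelings(self):
        # every pair of labelings of 4 items over 3 labels
        labelings = list(itertools.product(range(3), repeat=4))
        for a in labelings[::7]:
            for b in labelings:
                assert mf.adjusted_rand_index(a, b) == pytest.approx(
                    _pair_counting_ari(a, b), abs=1e-12
                )

    def test_matches_sklearn_on_random(self, rng):
        for _ in range(25):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 5, 30)
            assert mf.adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            mf.adjusted_rand_index([1, 2], [1, 2, 3])


class TestHVGBaseline:
    def test_constant_gene_last(self, rng):
        m = rng.poisson(20, (10, 100)).astype(float)
        m[3] = 7.0
        views = make_views(m)
        ranked = mf.hvg_baseline(views, n_hvg=10)
        assert ranked[-1] == "g3"

    def test_planted_modules_rank_high(self, planted_sim):
        ref, truth = planted_sim
        views = mf.normalize_views(ref)
        top = set(mf.hvg_baseline(views, n_hvg=45))
        planted = set(truth.module_membership)
        assert len(planted & top) / len(planted) >= 0.9

    def test_full_set_identity(self, small_views):
        assert set(mf.hvg_baseline(small_views, n_hvg=50)) == set(small_views.gene_ids)

    def test_too_many_requested(self, small_views):
        with pytest.raises(ValueError, match="exceeds"):
            mf.hvg_baseline(small_views, n_hvg=51)
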