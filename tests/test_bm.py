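"""Brownian rate estimation: likelihoods, fits, CIs, LRT, map pooling."""

import numpy as np
import pytest

from phylorates.bm import (
    bm_loglik,
    fit_multi_rate,
    fit_single_rate,
    lrt_single_vs_multi,
    pool_over_maps,
    preprocess_trait,
    rate_ci,
    regime_covariances,
)
from phylorates.mk import STATES, MapEnsemble, MkModel, StochasticMap, fit_mk, sample_stochastic_maps
from phylorates.simulate import (
    SimConfig,
    simulate_bm_multirate,
    simulate_discrete,
    simulate_tree,
)
from phylorates.tree import read_newick, vcv_matrix

from conftest import random_tree


def contrasts_loglik(tree, y_by_label, sigma2, mu):
    """Independent pruning-algorithm likelihood (no matrix algebra).

    Standard Brownian-motion pruning: each contrast contributes a normal
    density with variance sigma2 * (sum of adjusted branch lengths); the
    root value contributes N(mu, sigma2 * v_root).
    """
    value, vlen = {}, {}
    lnl = 0.0
    for node in tree.root.postorder():
        if node.is_leaf():
            value[node.label] = y_by_label[node.label]
            vlen[node.label] = node.length
            continue
        a, b = node.children
        va, vb = vlen[a.label], vlen[b.label]
        v = va + vb
        diff = value[a.label] - value[b.label]
        lnl += -0.5 * (np.log(2 * np.pi * sigma2 * v) + diff**2 / (sigma2 * v))
        value[node.label] = (value[a.label] * vb + value[b.label] * va) / v
        vlen[node.label] = node.length + va * vb / v
    v_root = vlen[tree.root.label]
    x_root = value[tree.root.label]
    lnl += -0.5 * (np.log(2 * np.pi * sigma2 * v_root)
                   + (x_root - mu) ** 2 / (sigma2 * v_root))
    return lnl


def true_history_map(dataset_tree, q, seed):
    tips, history = simulate_discrete(dataset_tree, q, seed=seed)
    return tips, StochasticMap(dataset_tree, history)


class TestLoglik:
    def test_two_tip_star_closed_form(self):
        C = np.eye(2)
        got = bm_loglik(C, np.array([0.0, 2.0]), 1.0, 1.0)
        assert got == pytest.approx(-np.log(2 * np.pi) - 1.0, abs=1e-12)

    def test_large_rate_drives_loglik_down(self):
        C = np.eye(2)
        y = np.array([0.0, 2.0])
        assert bm_loglik(C, y, 1e8, 1.0) < bm_loglik(C, y, 1.0, 1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            bm_loglik(np.eye(3), np.array([0.0, 1.0]), 1.0, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_contrasts_oracle(self, seed):
        """GLS-matrix likelihood equals the pruning likelihood (1e-8)."""
        tree = random_tree(n_tips=10, seed=400 + seed)
        rng = np.random.default_rng(seed)
        labels = tree.tip_labels
        y = rng.normal(size=10)
        sigma2 = float(rng.uniform(0.05, 0.5))
        mu = float(rng.normal())
        got = bm_loglik(vcv_matrix(tree), y, sigma2, mu)
        oracle = contrasts_loglik(tree, dict(zip(labels, y)), sigma2, mu)
        assert got == pytest.approx(oracle, abs=1e-8)


class TestSingleRate:
    def test_star_hand_calculation(self):
        star = read_newick("(A:1,B:1);")
        s2, mu, lnl = fit_single_rate(star, np.array([0.0, 2.0]))
        assert mu == pytest.approx(1.0)
        assert s2 == pytest.approx(1.0)
        assert lnl == pytest.approx(-np.log(2 * np.pi) - 1.0)

    def test_constant_trait_zero_rate(self):
        tree = random_tree(n_tips=6, seed=1)
        with pytest.warns(RuntimeWarning):
            s2, mu, _ = fit_single_rate(tree, np.full(6, 2.5))
        assert s2 == 0.0
        assert mu == pytest.approx(2.5)

    def test_recovery_mean_within_5pct(self):
        """Mean sigma2-hat over replicates within 5% of 0.1 (100 tips)."""
        s2_true, reps = 0.1, 200
        tree = random_tree(n_tips=100, seed=55)
        hist = {n.label: [("liana", n.length)] for n in tree.nodes}
        labels = tree.tip_labels
        ests = []
        for seed in range(reps):
            vals = simulate_bm_multirate(tree, hist, {"liana": s2_true}, 0.0,
                                         seed=seed)
            y = np.array([vals[lab] for lab in labels])
            s2, _, _ = fit_single_rate(tree, y)
            ests.append(s2)
        assert abs(np.mean(ests) - s2_true) < 0.05 * s2_true


class TestRegimeCovariances:
    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_sums_to_vcv(self, seed):
        tree = random_tree(n_tips=20, seed=500 + seed)
        tips, _ = simulate_discrete(tree, 0.03, seed=seed)
        model = MkModel(Q=np.array([[-0.03, 0.03], [0.03, -0.03]]))
        ens = sample_stochastic_maps(tree, model, tips, n_maps=3, seed=seed)
        C = vcv_matrix(tree).values
        for smap in ens.maps:
            Cs = regime_covariances(smap)
            np.testing.assert_allclose(
                Cs["liana"] + Cs["tree"], C, atol=1e-9
            )

    def test_each_regime_psd(self):
        tree = random_tree(n_tips=15, seed=77)
        tips, smap = true_history_map(tree, 0.05, seed=2)
        for mat in regime_covariances(smap).values():
            assert np.linalg.eigvalsh(mat).min() > -1e-9


class TestMultiRate:
    def test_single_state_map_degenerates_to_single_rate(self):
        tree = random_tree(n_tips=12, seed=9)
        hist = {n.label: [("liana", n.length if n.parent else 0.0)]
                for n in tree.nodes}
        smap = StochasticMap(tree, hist)
        y = np.random.default_rng(0).normal(size=12)
        with pytest.raises(ValueError, match="zero mapped time"):
            fit_multi_rate(smap, y)

    def test_label_swap_swaps_rates(self):
        tree = random_tree(n_tips=30, seed=12)
        tips, smap = true_history_map(tree, 0.05, seed=4)
        rng = np.random.default_rng(1)
        vals = simulate_bm_multirate(tree, smap.segments,
                                     {"liana": 0.2, "tree": 0.05}, 0.0, seed=7)
        y = np.array([vals[lab] for lab in tree.tip_labels])
        sig, _, lnl = fit_multi_rate(smap, y)
        flipped = StochasticMap(tree, {
            lab: [("liana" if s == "tree" else "tree", d) for s, d in segs]
            for lab, segs in smap.segments.items()
        })
        sig2, _, lnl2 = fit_multi_rate(flipped, y)
        assert sig2["liana"] == pytest.approx(sig["tree"], rel=1e-9)
        assert sig2["tree"] == pytest.approx(sig["liana"], rel=1e-9)
        assert lnl2 == pytest.approx(lnl, abs=1e-9)

    def test_nesting_multi_at_least_single(self):
        tree = random_tree(n_tips=40, seed=14)
        tips, smap = true_history_map(tree, 0.04, seed=5)
        vals = simulate_bm_multirate(tree, smap.segments,
                                     {"liana": 0.1, "tree": 0.1}, 0.0, seed=8)
        y = np.array([vals[lab] for lab in tree.tip_labels])
        sig, _, lnl_multi = fit_multi_rate(smap, y)
        _, _, lnl_single = fit_single_rate(tree, y)
        assert lnl_multi >= lnl_single - 1e-6

    def test_recovery_small_sample(self):
        """Quick parameter-recovery sanity check (full study-scale suite in
        the acceptance tests)."""
        rates = {"liana": 0.148, "tree": 0.083}
        est_l, est_t = [], []
        for seed in range(20):
            tree = simulate_tree(SimConfig(n_tips=134, seed=3000 + seed,
                                           target_counts=None))
            tips, smap = true_history_map(tree, 0.02, seed=seed)
            if len(set(tips.values())) < 2:
                continue
            vals = simulate_bm_multirate(tree, smap.segments, rates, 0.0,
                                         seed=seed)
            y = np.array([vals[lab] for lab in tree.tip_labels])
            try:
                sig, _, _ = fit_multi_rate(smap, y)
            except ValueError:
                continue
            est_l.append(sig["liana"])
            est_t.append(sig["tree"])
        assert abs(np.median(est_l) - 0.148) < 0.25 * 0.148
        assert abs(np.median(est_t) - 0.083) < 0.25 * 0.083


class TestLRT:
    def test_identical_models_give_p_one(self):
        stat, p = lrt_single_vs_multi(-100.0, -100.0)
        assert stat == 0.0 and p == 1.0

    def test_negative_diff_clipped(self):
        stat, p = lrt_single_vs_multi(-101.0, -100.0)
        assert stat == 0.0 and p == 1.0

    def test_chi2_mapping(self):
        from scipy.stats import chi2

        stat, p = lrt_single_vs_multi(-98.0, -100.0)
        assert stat == pytest.approx(4.0)
        assert p == pytest.approx(float(chi2.sf(4.0, 1)))


class TestRateCI:
    def test_ci_contains_estimate(self):
        tree = random_tree(n_tips=50, seed=20)
        hist = {n.label: [("liana", n.length if n.parent else 0.0)]
                for n in tree.nodes}
        vals = simulate_bm_multirate(tree, hist, {"liana": 0.1}, 0.0, seed=1)
        y = np.array([vals[lab] for lab in tree.tip_labels])
        s2, _, _ = fit_single_rate(tree, y)
        lo, hi = rate_ci(tree, y)
        assert lo < s2 < hi

    def test_ci_narrows_with_sample_size(self):
        widths = {}
        for n in (20, 100):
            tree = random_tree(n_tips=n, seed=21)
            hist = {nd.label: [("liana", nd.length if nd.parent else 0.0)]
                    for nd in tree.nodes}
            vals = simulate_bm_multirate(tree, hist, {"liana": 0.1}, 0.0,
                                         seed=2)
            y = np.array([vals[lab] for lab in tree.tip_labels])
            lo, hi = rate_ci(tree, y)
            widths[n] = np.log(hi) - np.log(lo)
        assert widths[100] < widths[20]

    def test_multi_rate_ci_contains_estimate(self):
        tree = random_tree(n_tips=40, seed=22)
        tips, smap = true_history_map(tree, 0.05, seed=6)
        vals = simulate_bm_multirate(tree, smap.segments,
                                     {"liana": 0.15, "tree": 0.08}, 0.0,
                                     seed=3)
        y = np.array([vals[lab] for lab in tree.tip_labels])
        sig, _, _ = fit_multi_rate(smap, y)
        for state in STATES:
            lo, hi = rate_ci(smap, y, state=state)
            assert lo < sig[state] < hi


class TestPoolOverMaps:
    def _ensemble_and_y(self, n_maps=6, seed=0):
        tree = random_tree(n_tips=40, seed=30)
        tips, _ = simulate_discrete(tree, 0.03, seed=seed)
        model = fit_mk(tree, tips)
        ens = sample_stochastic_maps(tree, model, tips, n_maps=n_maps,
                                     seed=seed)
        vals = simulate_bm_multirate(
            tree, ens.maps[0].segments, {"liana": 0.12, "tree": 0.06}, 0.0,
            seed=seed,
        )
        y = np.array([vals[lab] for lab in tree.tip_labels])
        return tree, ens, y

    def test_identical_maps_equal_single_map_fit(self):
        tree, ens, y = self._ensemble_and_y()
        clone = MapEnsemble([ens.maps[0]] * 4, ens.model, 0)
        pooled = pool_over_maps(clone, y, compute_ci=False)
        sig, mu, lnl = fit_multi_rate(ens.maps[0], y)
        for s in STATES:
            assert pooled.sigma2_by_state[s] == pytest.approx(sig[s], rel=1e-8)
            assert pooled.sigma2_sd_by_state[s] == pytest.approx(0.0, abs=1e-10)
        assert pooled.loglik_multi == pytest.approx(lnl, abs=1e-8)

    def test_pooled_estimate_inside_per_map_envelope(self):
        tree, ens, y = self._ensemble_and_y()
        pooled = pool_over_maps(ens, y, compute_ci=False)
        per_map = [fit_multi_rate(m, y)[0] for m in ens.maps]
        for s in STATES:
            vals = [pm[s] for pm in per_map]
            assert min(vals) - 1e-12 <= pooled.sigma2_by_state[s] <= max(vals) + 1e-12

    def test_dispersion_shrinks_when_history_certain(self):
        """Across-map SD of rates decreases as the Mk rate -> 0."""
        tree = random_tree(n_tips=60, seed=31)
        sds = {}
        for q, seed in ((0.005, 2), (0.08, 2)):
            tips, _ = simulate_discrete(tree, q, seed=seed)
            assert len(set(tips.values())) == 2
            model = MkModel(Q=np.array([[-q, q], [q, -q]]))
            ens = sample_stochastic_maps(tree, model, tips, n_maps=12,
                                         seed=seed)
            vals = simulate_bm_multirate(
                tree, ens.maps[0].segments, {"liana": 0.12, "tree": 0.06},
                0.0, seed=seed,
            )
            y = np.array([vals[lab] for lab in tree.tip_labels])
            pooled = pool_over_maps(ens, y, compute_ci=False)
            sds[q] = np.mean(list(pooled.sigma2_sd_by_state.values()))
        assert sds[0.005] < sds[0.08]


class TestPreprocess:
    def test_log_then_zscore(self):
        v = np.array([1.0, np.e, np.e**2])
        out = preprocess_trait(v, "auto")
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=0) == pytest.approx(1.0)
        np.testing.assert_allclose(out, preprocess_trait(np.log(v), "none"))

    def test_negative_values_skip_log(self):
        v = np.array([-1.0, 0.5, 2.0])
        out = preprocess_trait(v, "auto")
        assert out.std(ddof=0) == pytest.approx(1.0)

    def test_forced_log_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            preprocess_trait(np.array([-1.0, 2.0]), "log")
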