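import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ricemix import synth, twostep
from ricemix.datamodel import condition_means, profiles_to_matrix


def brute_force_2means(points):
    """Exhaustive optimal 2-partition by within-cluster sum of squares."""
    n = len(points)
    best, best_w = None, np.inf
    for mask in itertools.product([0, 1], repeat=n):
        mask = np.array(mask)
        if mask.sum() in (0, n):
            continue
        w = 0.0
        for lab in (0, 1):
            pts = points[mask == lab]
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
        if w < best_w - 1e-12:
            best_w, best = w, mask
    return best, best_w


def separated_scenario(seed, n_genes=200, frac_discordant=0.5):
    """8 planted components whose baselines dominate the +/-1.2 nitrogen
    offsets (within-component SD 0.2), so step 1 groups discordant genes
    with their parents and step 2 carries the discordance signal."""
    pm = []
    for k in range(8):
        b = 4.0 + 2.0 * k
        s = 1.2 if k % 2 == 0 else -1.2
        pm.append([b, b + s, b, b + s])
    cfg = synth.SimConfig(
        n_genes=n_genes, frac_null=0.0, frac_discordant=frac_discordant,
        K_true=8, profile_means=np.array(pm),
        covariance_params={"volume": 0.04}, noise_sd=0.2, seed=seed,
        timepoints=(21,))
    m, labels, flags = synth.simulate_expression(cfg)
    ids, X = profiles_to_matrix(condition_means(m, 21))
    return ids, X, labels, flags


class TestSplitByDensity:
    def test_rearrangement(self):
        hd, ld = twostep.split_by_density(np.array([[5.0, 4.0, 3.0, 1.0]]))
        np.testing.assert_array_equal(ld[0], [5.0, 4.0])
        np.testing.assert_array_equal(hd[0], [3.0, 1.0])

    def test_constant_profile(self):
        hd, ld = twostep.split_by_density(np.array([[2.0] * 4]))
        np.testing.assert_array_equal(hd, ld)

    def test_shapes(self):
        X = np.arange(120, dtype=float).reshape(30, 4)
        hd, ld = twostep.split_by_density(X)
        assert hd.shape == ld.shape == (30, 2)


class TestKmeans2:
    def test_matches_brute_force_on_worked_example(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [9.0, 9.0], [9.0, 10.0]])
        labels, centers = twostep.kmeans2(pts, seed=0)
        truth, w_opt = brute_force_2means(pts)
        assert adjusted_rand_score(truth, labels) == 1.0
        np.testing.assert_allclose(centers[np.argsort(centers[:, 0])],
                                   [[0.0, 0.5], [9.0, 9.5]], atol=1e-12)
        w = sum(((pts[labels == l] - pts[labels == l].mean(axis=0)) ** 2).sum()
                for l in (0, 1))
        assert w == pytest.approx(w_opt)

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            pts = rng.normal(size=(8, 2))
            labels, _ = twostep.kmeans2(pts, seed=2, n_starts=20)
            truth, w_opt = brute_force_2means(pts)
            centers = np.array([pts[labels == l].mean(axis=0) for l in (0, 1)])
            w = sum(((pts[labels == l] - centers[l]) ** 2).sum() for l in (0, 1))
            assert w == pytest.approx(w_opt, rel=1e-9)

    def test_identical_points_convention(self):
        pts = np.ones((5, 2))
        labels, centers = twostep.kmeans2(pts, seed=0)
        assert np.all(labels == 0)
        np.testing.assert_array_equal(centers[0], centers[1])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            twostep.kmeans2(np.ones((1, 2)), seed=0)


class TestMatchLabels:
    def test_matches_minimal_disagreement_on_clear_trends(self):
        """When one density's cluster order is flipped, trend matching
        realigns it — equivalently the minimal-Hamming matching, checked by
        brute force over both pairings."""
        ld_labels = np.array([0] * 5 + [1] * 5)
        hd_labels = 1 - ld_labels  # same structure, flipped indices
        ld_centers = np.array([[5.0, 7.0], [5.0, 5.0]])   # trend 2, 0
        hd_centers = np.array([[5.0, 5.0], [5.0, 7.0]])   # trend 0, 2
        matched, centers = twostep.match_labels(hd_labels, hd_centers,
                                                ld_labels, ld_centers)
        disagreements = [(matched != ld_labels).sum(),
                         ((1 - matched) != ld_labels).sum()]
        assert (matched != ld_labels).sum() == min(disagreements) == 0
        np.testing.assert_array_equal(centers, hd_centers[::-1])

    def test_identity_kept_when_aligned(self):
        labels = np.array([0, 0, 1, 1])
        centers = np.array([[5.0, 7.0], [5.0, 5.0]])
        matched, _ = twostep.match_labels(labels, centers, labels, centers)
        np.testing.assert_array_equal(matched, labels)


class TestStep2Component:
    def test_concordant_component_all_false(self):
        rng = np.random.default_rng(0)
        X = np.empty((40, 4))
        # half respond to nitrogen under both densities, half never do
        X[:20] = [8.0, 10.0, 8.0, 10.0]
        X[20:] = [8.0, 8.0, 8.0, 8.0]
        X += rng.normal(0, 0.05, X.shape)
        *_, disc = twostep.step2_component(X, seed=1)
        assert not disc.any()

    def test_planted_discordance_recovered(self):
        ids, X, labels, flags = separated_scenario(seed=42, n_genes=160)
        hits = total = 0
        for k in range(8):
            idx = np.flatnonzero(labels == k)
            if idx.size < 4:
                continue
            *_, disc = twostep.step2_component(X[idx], seed=int(k))
            hits += int(np.sum(disc == flags[idx]))
            total += idx.size
        assert hits / total >= 0.9

    def test_gpcm_and_kmeans_agree_on_separated_data(self):
        rng = np.random.default_rng(3)
        X = np.empty((60, 4))
        X[:30] = [6.0, 8.0, 6.0, 8.0]
        X[30:] = [6.0, 6.0, 6.0, 6.0]
        X += rng.normal(0, 0.05, X.shape)
        *_, d_km = twostep.step2_component(X, method="kmeans", seed=4)
        *_, d_gp = twostep.step2_component(X, method="gpcm", seed=4)
        np.testing.assert_array_equal(d_km, d_gp)


class TestRunTwoStep:
    def test_end_to_end_recovery(self):
        ids, X, labels, flags = separated_scenario(seed=7)
        res = twostep.run_two_step(ids, X, strategy="gpcm-kmeans", seed=11,
                                   G_range=range(1, 9), n_starts=4)
        assert adjusted_rand_score(labels, res.step1_labels) >= 0.9
        got = res.discordance_flags()
        truth = dict(zip(ids, flags))
        tp = sum(got[g] and truth[g] for g in got)
        fn = sum((not got[g]) and truth[g] for g in got)
        fp = sum(got[g] and not truth[g] for g in got)
        tn = sum((not got[g]) and not truth[g] for g in got)
        assert tp / (tp + fn) >= 0.9
        assert tn / (tn + fp) >= 0.9

    def test_small_components_skipped(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.05, (3, 4)),
                       rng.normal(6, 0.05, (20, 4))])
        ids = [f"g{i}" for i in range(len(X))]
        res = twostep.run_two_step(ids, X, seed=0, G_range=[2], n_starts=3)
        sizes = {c: len(cs.gene_ids) for c, cs in res.components.items()}
        small = min(sizes, key=sizes.get)
        assert res.components[small].skipped
        assert res.components[small].discordant is None

    def test_gene_order_invariance(self):
        ids, X, *_ = separated_scenario(seed=13, n_genes=120)
        res = twostep.run_two_step(ids, X, seed=3, G_range=[8], n_starts=4)
        perm = np.random.default_rng(0).permutation(len(ids))
        res_p = twostep.run_two_step([ids[i] for i in perm], X[perm], seed=3,
                                     G_range=[8], n_starts=4)
        assert res.discordance_flags() == res_p.discordance_flags()

    def test_single_density_mode_has_no_discordance(self):
        ids, X, *_ = separated_scenario(seed=17, n_genes=80)
        res = twostep.run_two_step(ids, X, seed=5, G_range=[8], n_starts=3,
                                   step2_density="HD")
        for cs in res.components.values():
            assert cs.discordant is None
            if not cs.skipped:
                assert cs.ld_labels is None and cs.hd_labels is not None

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            twostep.run_two_step(["a", "b"], np.zeros((2, 4)), strategy="bogus")
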