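"""Polarity-invariant modified k-means, fit criteria, and label alignment."""

import itertools

import numpy as np
import pytest

from microstates.clustering import (ClusteringError, TemplateSet,
                                    TopographySet, align_labels,
                                    brute_force_alignment, compute_gev,
                                    cv_criterion, gmd, modified_kmeans,
                                    select_k, spatial_correlation)
from microstates.synthetic import make_canonical_templates


def _orth_maps(n_channels, k, rng):
    """k orthogonal zero-mean unit-norm maps."""
    m = rng.normal(size=(n_channels, n_channels))
    q, _ = np.linalg.qr(m - m.mean(axis=0, keepdims=True))
    maps = []
    for col in q.T:
        v = col - col.mean()
        n = np.linalg.norm(v)
        if n > 0.3:
            maps.append(v / n)
        if len(maps) == k:
            break
    return np.vstack(maps)


def _obs_from(templates, n, rng, noise=0.0):
    k = templates.shape[0]
    cls = rng.integers(k, size=n)
    amp = rng.uniform(0.5, 2.0, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    x = (amp * sign)[:, None] * templates[cls]
    if noise:
        x = x + rng.normal(0, noise, size=x.shape)
    return x, cls


class TestSpatialCorrelation:
    def test_identity_and_polarity(self, rng):
        u = rng.normal(size=8)
        assert spatial_correlation(u, u) == pytest.approx(1.0)
        assert spatial_correlation(u, -u, polarity_invariant=True) == \
            pytest.approx(1.0)
        assert spatial_correlation(u, -u, polarity_invariant=False) == \
            pytest.approx(-1.0)

    def test_matches_hand_pearson(self):
        u = np.array([1.0, 2.0, 0.0, -1.0])
        v = np.array([0.5, 1.0, 1.0, -2.0])
        uc, vc = u - u.mean(), v - v.mean()
        r = (uc @ vc) / np.sqrt((uc @ uc) * (vc @ vc))
        assert spatial_correlation(u, v, polarity_invariant=False) == \
            pytest.approx(r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ClusteringError):
            spatial_correlation(np.ones(4), np.array([1.0, 2, 3, 4]))


class TestGmd:
    def test_identical_shape_is_zero(self, rng):
        u = rng.normal(size=8)
        assert gmd(u, 3.0 * u) == pytest.approx(0.0, abs=1e-12)
        assert gmd(u, -2.0 * u) == pytest.approx(0.0, abs=1e-12)

    def test_relates_to_correlation(self, rng):
        u, v = rng.normal(size=8), rng.normal(size=8)
        r = spatial_correlation(u, v)
        assert gmd(u, v) == pytest.approx(np.sqrt(2 * (1 - r)), abs=1e-12)


class TestComputeGev:
    def test_exact_multiples_give_one(self, rng):
        t = _orth_maps(8, 3, rng)
        obs, cls = _obs_from(t, 30, rng)
        ts = TemplateSet(templates=t, channels=[f"C{i}" for i in range(8)],
                         labels=list("abc"))
        topo = TopographySet(maps=obs, channels=ts.channels)
        assert compute_gev(topo, ts, cls) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_observations_give_zero(self, rng):
        t = _orth_maps(8, 4, rng)
        ts = TemplateSet(templates=t[:2],
                         channels=[f"C{i}" for i in range(8)],
                         labels=list("ab"))
        obs, _ = _obs_from(t[2:], 20, rng)
        topo = TopographySet(maps=obs, channels=ts.channels)
        assign = np.zeros(20, dtype=int)
        assert compute_gev(topo, ts, assign) == pytest.approx(0.0, abs=1e-12)

    def test_matches_term_by_term_summation(self, rng):
        t = _orth_maps(8, 3, rng)
        ts = TemplateSet(templates=t, channels=[f"C{i}" for i in range(8)],
                         labels=list("abc"))
        maps = rng.normal(size=(20, 8))
        topo = TopographySet(maps=maps, channels=ts.channels)
        assign = rng.integers(3, size=20)
        num = den = 0.0
        for i in range(20):
            x = maps[i]
            gfp = np.sqrt(np.mean((x - x.mean()) ** 2))
            r = spatial_correlation(x, t[assign[i]])
            num += (gfp * r) ** 2
            den += gfp**2
        assert compute_gev(topo, ts, assign) == pytest.approx(num / den,
                                                              abs=1e-12)


class TestCvCriterion:
    def test_noise_free_fit_is_zero(self, rng):
        t = _orth_maps(8, 2, rng)
        obs, cls = _obs_from(t, 20, rng)
        ts = TemplateSet(templates=t, channels=[f"C{i}" for i in range(8)],
                         labels=list("ab"))
        topo = TopographySet(maps=obs, channels=ts.channels)
        assert cv_criterion(topo, ts, cls) == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_voltage_scaling(self, rng):
        t = _orth_maps(8, 2, rng)
        ts = TemplateSet(templates=t, channels=[f"C{i}" for i in range(8)],
                         labels=list("ab"))
        maps = rng.normal(size=(15, 8))
        assign = rng.integers(2, size=15)
        cv1 = cv_criterion(TopographySet(maps=maps, channels=ts.channels),
                           ts, assign)
        cv2 = cv_criterion(TopographySet(maps=2 * maps, channels=ts.channels),
                           ts, assign)
        assert cv2 == pytest.approx(4 * cv1, rel=1e-12)

    def test_matches_hand_summation(self, rng):
        t = _orth_maps(6, 2, rng)
        ts = TemplateSet(templates=t, channels=[f"C{i}" for i in range(6)],
                         labels=list("ab"))
        maps = rng.normal(size=(10, 6))
        assign = rng.integers(2, size=10)
        xc = maps - maps.mean(axis=1, keepdims=True)
        sigma2 = sum(xc[i] @ xc[i] - (t[assign[i]] @ xc[i]) ** 2
                     for i in range(10)) / (10 * (6 - 1))
        expected = sigma2 * ((6 - 1) / (6 - 1 - 2)) ** 2
        topo = TopographySet(maps=maps, channels=ts.channels)
        assert cv_criterion(topo, ts, assign) == pytest.approx(expected,
                                                               abs=1e-12)

    def test_too_few_channels_rejected(self, rng):
        t = _orth_maps(4, 3, rng)
        ts = TemplateSet(templates=t, channels=[f"C{i}" for i in range(4)],
                         labels=list("abc"))
        topo = TopographySet(maps=rng.normal(size=(10, 4)),
                             channels=ts.channels)
        with pytest.raises(ClusteringError):
            cv_criterion(topo, ts, np.zeros(10, dtype=int))


class TestModifiedKmeans:
    def test_noise_free_two_class_identifiability(self, rng):
        t = _orth_maps(8, 2, rng)
        obs, cls = _obs_from(t, 40, rng)
        topo = TopographySet(maps=obs, channels=[f"C{i}" for i in range(8)])
        ts, assign, diag = modified_kmeans(topo, 2, n_restarts=10, seed=1)
        assert ts.gev == pytest.approx(1.0, abs=1e-9)
        for row in ts.templates:
            best = max(spatial_correlation(row, t[0]),
                       spatial_correlation(row, t[1]))
            assert best > 0.999
        # partition matches generating classes up to permutation
        assert len({(c, a) for c, a in zip(cls, assign)}) == 2

    def test_polarity_invariance_of_partition(self, rng):
        t = _orth_maps(8, 2, rng)
        obs, _ = _obs_from(t, 40, rng, noise=0.3)
        topo = TopographySet(maps=obs, channels=[f"C{i}" for i in range(8)])
        flip = rng.choice([-1.0, 1.0], size=40)
        flipped = TopographySet(maps=flip[:, None] * obs,
                                channels=topo.channels)
        ts1, a1, _ = modified_kmeans(topo, 2, n_restarts=5, seed=3)
        ts2, a2, _ = modified_kmeans(flipped, 2, n_restarts=5, seed=3)
        np.testing.assert_array_equal(a1, a2)
        assert ts1.gev == pytest.approx(ts2.gev, abs=0)

    def test_attains_exhaustive_search_optimum(self, rng):
        """Small-instance global optimality vs brute-force enumeration."""
        for trial in range(5):
            maps = rng.normal(size=(8, 4))
            topo = TopographySet(maps=maps,
                                 channels=[f"C{i}" for i in range(4)])
            ts, assign, _ = modified_kmeans(topo, 2, n_restarts=50,
                                            seed=100 + trial)
            best = _exhaustive_best_gev(maps, 2)
            assert ts.gev == pytest.approx(best, abs=1e-9)

    def test_template_rows_zero_mean_unit_norm(self, rng):
        t = _orth_maps(8, 3, rng)
        obs, _ = _obs_from(t, 60, rng, noise=0.5)
        topo = TopographySet(maps=obs, channels=[f"C{i}" for i in range(8)])
        ts, _, _ = modified_kmeans(topo, 3, n_restarts=5, seed=0)
        np.testing.assert_allclose(ts.templates.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(ts.templates, axis=1), 1,
                                   atol=1e-9)

    def test_same_seed_reproducible(self, rng):
        obs = rng.normal(size=(30, 8))
        topo = TopographySet(maps=obs, channels=[f"C{i}" for i in range(8)])
        ts1, a1, d1 = modified_kmeans(topo, 3, n_restarts=5, seed=9)
        ts2, a2, d2 = modified_kmeans(topo, 3, n_restarts=5, seed=9)
        np.testing.assert_array_equal(ts1.templates, ts2.templates)
        np.testing.assert_array_equal(a1, a2)
        assert d1.restart_gev == d2.restart_gev

    def test_best_restart_has_maximal_gev(self, rng):
        obs = rng.normal(size=(40, 8))
        topo = TopographySet(maps=obs, channels=[f"C{i}" for i in range(8)])
        ts, _, diag = modified_kmeans(topo, 3, n_restarts=8, seed=2)
        assert ts.gev == pytest.approx(max(diag.restart_gev))

    def test_degenerate_inputs_rejected(self, rng):
        topo = TopographySet(maps=rng.normal(size=(3, 4)),
                             channels=list("abcd"))
        with pytest.raises(ClusteringError):
            modified_kmeans(topo, 4)
        same = np.tile(np.array([1.0, -1.0, 2.0, -2.0]), (6, 1))
        with pytest.raises(ClusteringError):
            modified_kmeans(TopographySet(maps=same, channels=list("abcd")),
                            2, n_restarts=2)


def _exhaustive_best_gev(maps, k):
    """Brute-force: all labelings, eigenvector template per cluster."""
    n, c = maps.shape
    xc = maps - maps.mean(axis=1, keepdims=True)
    total = np.sum(xc**2)
    best = -np.inf
    for bits in itertools.product(range(k), repeat=n):
        assign = np.array(bits)
        if len(set(bits)) < k:
            continue
        num = 0.0
        ok = True
        for j in range(k):
            members = xc[assign == j]
            scatter = members.T @ members
            w, v = np.linalg.eigh(scatter)
            tj = v[:, -1]
            tj = tj - tj.mean()
            nrm = np.linalg.norm(tj)
            if nrm == 0:
                ok = False
                break
            tj /= nrm
            num += np.sum((members @ tj) ** 2)
        if ok:
            best = max(best, num / total)
    return best


class TestSelectK:
    def test_singleton_range(self, rng):
        t = _orth_maps(10, 4, rng)
        obs, _ = _obs_from(t, 80, rng, noise=0.2)
        topo = TopographySet(maps=obs, channels=[f"C{i}" for i in range(10)])
        k, diag = select_k(topo, k_range=(4,), n_restarts=5, seed=0)
        assert k == 4
        assert len(diag.k_table) == 1

    def test_gev_non_decreasing_in_k(self, rng):
        t = _orth_maps(12, 4, rng)
        obs, _ = _obs_from(t, 100, rng, noise=0.5)
        topo = TopographySet(maps=obs, channels=[f"C{i}" for i in range(12)])
        _, diag = select_k(topo, k_range=(2, 3, 4, 5), n_restarts=10, seed=0)
        gevs = [diag.k_table[k][0] for k in (2, 3, 4, 5)]
        assert all(b >= a - 1e-6 for a, b in zip(gevs, gevs[1:]))

    def test_recovers_generating_k(self, rng):
        t = _orth_maps(16, 4, rng)
        obs, _ = _obs_from(t, 300, rng, noise=0.15)
        topo = TopographySet(maps=obs, channels=[f"C{i}" for i in range(16)])
        k, _ = select_k(topo, k_range=(4, 5, 6, 7), n_restarts=10, seed=0)
        assert k == 4


class TestAlignLabels:
    def test_identity_alignment(self, templates16):
        aligned = align_labels(templates16, templates16)
        assert aligned.labels == templates16.labels
        np.testing.assert_allclose(aligned.templates, templates16.templates)

    def test_permutation_and_sign_flips_inverted(self, templates16, rng):
        perm = rng.permutation(4)
        signs = rng.choice([-1.0, 1.0], size=4)
        shuffled = TemplateSet(
            templates=signs[:, None] * templates16.templates[perm],
            channels=templates16.channels,
            labels=[str(i) for i in range(4)])
        aligned = align_labels(shuffled, templates16)
        assert aligned.labels == templates16.labels
        for i in range(4):
            assert spatial_correlation(aligned.templates[i],
                                       templates16.templates[i]) > 0.999

    def test_noisy_alignment_matches_brute_force(self, templates16, rng):
        for trial in range(5):
            perm = rng.permutation(4)
            noisy = templates16.templates[perm] \
                + rng.normal(0, 0.2 / 4, size=(4, 16))
            noisy = noisy - noisy.mean(axis=1, keepdims=True)
            noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
            shuffled = TemplateSet(templates=noisy,
                                   channels=templates16.channels,
                                   labels=[str(i) for i in range(4)])
            best_perm = brute_force_alignment(shuffled, templates16)
            aligned = align_labels(shuffled, templates16)
            np.testing.assert_allclose(
                aligned.templates,
                np.sign([(shuffled.templates[best_perm[i]]
                          @ templates16.templates[i]) or 1.0
                         for i in range(4)])[:, None]
                * shuffled.templates[best_perm])

    def test_k_mismatch_rejected(self, templates16, montage16):
        five = make_canonical_templates(montage16, K=5, seed=0)
        with pytest.raises(ClusteringError):
            align_labels(five, templates16)
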