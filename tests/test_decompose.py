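"""Extension, whitening, fixed-point separation, peak classing, duplicates."""

import numpy as np
import pytest

from mupool.decompose import (
    DecompositionConfig,
    MotorUnitEstimate,
    common_discharge_fraction,
    decompose,
    detect_discharges,
    extend,
    find_duplicates,
    fixed_point_source,
    silhouette_measure,
    whiten,
)
from mupool.tracking import rate_of_agreement

FS = 2048.0


class TestExtend:
    @pytest.mark.parametrize(
        "channels,target,factor,rows",
        [(236, 1000, 5, 1180), (64, 1000, 16, 1024), (10, 5, 1, 10)],
    )
    def test_extension_factor_rule(self, channels, target, factor, rows):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(channels, 400))
        ext, r = extend(x, target)
        assert r == factor
        assert ext.shape == (rows, 400)

    def test_factor_one_is_identity(self):
        x = np.arange(20.0).reshape(2, 10)
        ext, r = extend(x, 2)
        assert r == 1
        np.testing.assert_array_equal(ext, x)

    def test_delayed_rows_with_leading_zeros(self):
        x = np.arange(1.0, 9.0).reshape(1, 8)
        ext, r = extend(x, 3)
        assert r == 3
        np.testing.assert_array_equal(ext[0], x[0])
        np.testing.assert_array_equal(ext[1], [0, 1, 2, 3, 4, 5, 6, 7])
        np.testing.assert_array_equal(ext[2], [0, 0, 1, 2, 3, 4, 5, 6])


class TestWhiten:
    def test_white_noise_unit_diagonal(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 100_000))
        obs = whiten(x)
        cov = obs.matrix @ obs.matrix.T / obs.matrix.shape[1]
        assert np.all(np.abs(np.diag(cov) - 1.0) < 0.05)

    def test_full_rank_mixture_whitens_to_identity(self):
        rng = np.random.default_rng(2)
        s = rng.laplace(size=(8, 5000))
        a = rng.normal(size=(8, 8))
        obs = whiten(a @ s)
        cov = obs.matrix @ obs.matrix.T / obs.matrix.shape[1]
        assert np.max(np.abs(cov - np.eye(8))) < 1e-6

    def test_already_white_input_keeps_covariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 4000))
        z1 = whiten(x).matrix
        z2 = whiten(z1).matrix
        c1 = z1 @ z1.T / z1.shape[1]
        c2 = z2 @ z2.T / z2.shape[1]
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_rank_deficient_input_is_regularised(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 2000))
        x = np.vstack([x, x[0]])  # duplicated channel
        obs = whiten(x)
        assert np.all(np.isfinite(obs.matrix))

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            whiten(np.zeros((4, 100)))


def _sparse_mixture(seed=0, n_ch=12, n=20000, rate_hz=8.0, fs=FS):
    """One heavy-tailed sparse source embedded among Gaussian channels."""
    rng = np.random.default_rng(seed)
    spikes = np.cumsum(rng.integers(int(fs / rate_hz * 0.8), int(fs / rate_hz * 1.2), 150))
    spikes = spikes[spikes < n - 10]
    src = np.zeros(n)
    src[spikes] = 10.0
    mix = rng.normal(size=(n_ch, 1))
    x = mix @ src[None, :] + 0.1 * rng.normal(size=(n_ch, n))
    return x, spikes


class TestFixedPoint:
    def test_recovers_embedded_sparse_source(self):
        x, spikes = _sparse_mixture(seed=5)
        obs = whiten(x)
        cfg = DecompositionConfig(target_extended_channels=1)
        t0 = int(np.argmax(np.sum(obs.matrix**2, axis=0)))
        w = fixed_point_source(obs, obs.matrix[:, t0], cfg)
        assert w is not None
        assert np.linalg.norm(w) == pytest.approx(1.0)
        detected, _, _ = detect_discharges(w @ obs.matrix, FS, cfg)
        assert rate_of_agreement(detected, spikes, FS, tol_ms=1.0) >= 0.95

    def test_fixed_point_is_stable(self):
        x, _ = _sparse_mixture(seed=6)
        obs = whiten(x)
        cfg = DecompositionConfig(target_extended_channels=1)
        w = fixed_point_source(obs, obs.matrix[:, 100], cfg)
        w2 = fixed_point_source(obs, w, cfg)
        assert np.linalg.norm(w2) == pytest.approx(1.0)
        assert abs(abs(float(w @ w2)) - 1.0) < 1e-3

    def test_gaussian_noise_converges_without_error(self):
        rng = np.random.default_rng(7)
        obs = whiten(rng.normal(size=(10, 8000)))
        w = fixed_point_source(obs, rng.normal(size=10), DecompositionConfig())
        assert w is None or np.linalg.norm(w) == pytest.approx(1.0)

    def test_zero_init_rejected(self):
        rng = np.random.default_rng(8)
        obs = whiten(rng.normal(size=(4, 1000)))
        with pytest.raises(ValueError):
            fixed_point_source(obs, np.zeros(4), DecompositionConfig())


class TestDetectDischarges:
    def test_two_amplitude_classes_split_at_centroids(self):
        rng = np.random.default_rng(9)
        n = 60000
        train = np.zeros(n)
        big = np.arange(500, n - 500, (n - 1000) // 20)[:20]
        train[big] = 10.0
        small = rng.choice(
            np.setdiff1d(np.arange(500, n - 500, 25), big), 200, replace=False
        )
        train[small] = 1.0
        discharges, peaks, labels = detect_discharges(train, FS)
        # oracle: threshold at the midpoint of the squared amplitudes
        oracle = np.sort(np.flatnonzero(train**2 > (100 + 1) / 2))
        np.testing.assert_array_equal(np.sort(discharges), oracle)

    def test_identical_peaks_degenerate(self):
        train = np.zeros(5000)
        train[::100] = 2.0
        with pytest.warns(UserWarning):
            discharges, peaks, labels = detect_discharges(train, FS)
        assert np.all(labels == 1)

    def test_empty_train(self):
        discharges, peaks, labels = detect_discharges(np.array([]), FS)
        assert discharges.size == 0


class TestSilhouette:
    def test_well_separated_classes(self):
        amps = np.array([10.0, 10.1, 0.1, 0.2])
        labels = np.array([1, 1, 0, 0])
        val = silhouette_measure(amps, labels)
        # direct formula: a = within-spike distance, b = mean distance to noise
        s1 = (np.mean([9.9, 9.8]) - 0.1) / np.mean([9.9, 9.8])
        s2 = (np.mean([10.0, 9.9]) - 0.1) / np.mean([10.0, 9.9])
        assert val == pytest.approx(np.mean([s1, s2]), abs=1e-12)
        assert val > 0.95

    def test_identically_distributed_classes_near_zero(self):
        rng = np.random.default_rng(10)
        vals = []
        for _ in range(100):
            amps = rng.normal(5.0, 1.0, 60)
            labels = np.r_[np.ones(30, dtype=int), np.zeros(30, dtype=int)]
            vals.append(silhouette_measure(amps, labels))
        assert abs(np.mean(vals)) < 0.05

    def test_single_class_sentinel(self):
        assert np.isnan(silhouette_measure(np.array([1.0, 2.0]), np.array([1, 1])))


def _estimate(discharges, isi_cov=0.1):
    return MotorUnitEstimate(
        separation_vector=np.ones(3) / np.sqrt(3),
        pulse_train=np.array([]),
        discharges=np.asarray(discharges, dtype=np.int64),
        silhouette=0.95,
        isi_cov=isi_cov,
    )


class TestDuplicates:
    def test_identical_trains_are_duplicates(self):
        t = np.arange(100, 20000, 205)
        clusters, retained = find_duplicates([_estimate(t, 0.2), _estimate(t, 0.1)], FS)
        assert sorted(map(len, clusters)) == [2]
        assert retained == [1]  # lowest ISI CoV wins

    def test_shifted_train_still_duplicate(self):
        t = np.arange(100, 20000, 205)
        shift = int(0.010 * FS)  # 10 ms
        clusters, _ = find_duplicates([_estimate(t), _estimate(t + shift)], FS)
        assert len(clusters) == 1 and len(clusters[0]) == 2

    def test_independent_trains_share_few_discharges(self):
        rng = np.random.default_rng(11)
        fracs = []
        for _ in range(100):
            a = np.cumsum(rng.integers(150, 260, 300))
            b = np.cumsum(rng.integers(150, 260, 300))
            a, b = a[a < 30 * FS], b[b < 30 * FS]
            frac, _ = common_discharge_fraction(a, b, FS, tol_ms=0.5, max_lag_ms=0.0)
            fracs.append(frac)
        assert np.mean(fracs) < 0.05


class TestDecompose:
    def test_toy_mixture_fully_recovered(self, toy_recording, toy_decomposition):
        """Noise-free, non-overlapping 5-unit mixture: every unit at RoA 1.0."""
        res = toy_decomposition
        assert len(res.units) == 5
        matched = set()
        for est in res.units:
            roas = [
                rate_of_agreement(est.discharges, t, FS, tol_ms=1.0)
                for t in toy_recording.truth_spikes
            ]
            best = int(np.argmax(roas))
            assert roas[best] == 1.0
            matched.add(best)
        assert matched == set(range(5))

    def test_accepted_units_meet_silhouette_threshold(self, toy_decomposition):
        for unit in toy_decomposition.units:
            assert unit.silhouette >= 0.9
            assert np.all(np.diff(unit.discharges) > 0)

    def test_separation_vectors_pairwise_orthogonal(self, toy_decomposition):
        vecs = np.array([u.separation_vector for u in toy_decomposition.units])
        gram = vecs @ vecs.T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6

    def test_pure_noise_yields_zero_units(self, grid, toy_cfg):
        from mupool.synth import SyntheticRecording
        from conftest import make_pool

        rng = np.random.default_rng(12)
        rec = SyntheticRecording(
            signals=rng.normal(size=(grid.n_channels, 16000)),
            fs=FS,
            force=np.zeros(16000),
            truth_spikes=[],
            pool=make_pool(rt=[10.0]),
            geometry=grid,
        )
        res = decompose(rec, toy_cfg)
        assert res.units == []

    def test_determinism(self, toy_recording, toy_cfg, toy_decomposition):
        res2 = decompose(toy_recording, toy_cfg)
        assert len(res2.units) == len(toy_decomposition.units)
        for a, b in zip(toy_decomposition.units, res2.units):
            np.testing.assert_array_equal(a.discharges, b.discharges)
            np.testing.assert_allclose(a.separation_vector, b.separation_vector)
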