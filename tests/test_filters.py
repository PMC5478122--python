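import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preictal.filters import (
    DegenerateOperatorError,
    FilterWeights,
    MomentSet,
    PairStream,
    apply_filters,
    estimate_filter,
    estimate_single,
    matvec,
    power_iteration,
)
from preictal.spectral import BandDefinition, SpectralTensor, log_spectrum

from conftest import make_clip


def dense_matrix(method: str, X0: np.ndarray, X1: np.ndarray) -> np.ndarray:
    """Densely assembled objective matrix — the oracle the matvecs must equal."""
    m0, m1 = X0.mean(0), X1.mean(0)
    S0 = X0.T @ X0 / len(X0)
    S1 = X1.T @ X1 / len(X1)
    if method == "DS":
        return S0 - S1
    if method == "VAR":
        return S0 - S1 - np.outer(m0, m0) + np.outer(m1, m1)
    if method == "TVM":
        return S0 - S1 + np.outer(m1 - m0, m1) + np.outer(m1, m1 - m0)
    if method == "SqD":
        return S0 + S1 - np.outer(m0, m1) - np.outer(m1, m0)
    raise ValueError(method)


def random_dataset(rng, d=None, n0=None, n1=None):
    d = d or rng.integers(2, 13)
    n0 = n0 or rng.integers(5, 40)
    n1 = n1 or rng.integers(5, 40)
    loc = rng.standard_normal(d)
    X0 = loc + rng.standard_normal((n0, d))
    X1 = loc + 0.5 * rng.standard_normal(d) + 1.3 * rng.standard_normal((n1, d))
    return X0, X1


class TestMomentSet:
    def test_means_exact(self):
        ms = MomentSet([[1, 0], [3, 0]], [[0, 1], [0, 3]])
        np.testing.assert_allclose(ms.mean0, [2, 0])
        np.testing.assert_allclose(ms.mean1, [0, 2])

    def test_second_moment_matvec_by_hand(self):
        ms = MomentSet([[1, 0], [3, 0]], [[0, 1], [0, 3]])
        np.testing.assert_allclose(ms.second0([1, 0]), [5, 0])  # (1^2 + 3^2)/2
        np.testing.assert_allclose(ms.second1([0, 1]), [0, 5])

    def test_single_sample_class_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            MomentSet([[1, 0]], [[0, 1], [0, 3]])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            MomentSet(np.zeros((3, 2)), np.zeros((3, 4)))


class TestMatvec:
    def test_ds_diagonal_arithmetic(self):
        # exact moments diag(4,1) vs diag(1,2) via sign-balanced four-point samples
        s = np.sqrt(2)
        X0 = np.array([[2.0, 1.0], [2.0, -1.0], [-2.0, 1.0], [-2.0, -1.0]])
        X1 = np.array([[1.0, s], [1.0, -s], [-1.0, s], [-1.0, -s]])
        ms = MomentSet(X0, X1)
        np.testing.assert_allclose(matvec("DS", ms, [1.0, 0.0]), [3.0, 0.0])

    @pytest.mark.parametrize("method", ["DS", "VAR", "TVM", "SqD"])
    def test_matches_dense_assembly(self, method, rng):
        for _ in range(10):
            X0, X1 = random_dataset(rng)
            ms = MomentSet(X0, X1)
            v = rng.standard_normal(X0.shape[1])
            np.testing.assert_allclose(
                matvec(method, ms, v), dense_matrix(method, X0, X1) @ v, atol=1e-10
            )

    def test_sqd_paired_degenerate_rank_one(self):
        """When every difference Z - Y is (3, 4), M v = (v . d) d for d = (3, 4)."""
        y = np.array([5.0, -2.0])
        X1 = np.tile(y, (3, 1))
        X0 = np.tile(y + np.array([3.0, 4.0]), (4, 1))
        ms = MomentSet(X0, X1)
        np.testing.assert_allclose(matvec("SqD", ms, [1.0, 0.0]), [9.0, 12.0])
        pairs = PairStream("sampled_pairs", seed=3)
        np.testing.assert_allclose(
            matvec("SqD", ms, [1.0, 0.0], pairs=pairs), [9.0, 12.0]
        )

    def test_sampled_pairs_mean_converges_to_independent_moments(self, rng):
        X0, X1 = random_dataset(rng, d=6, n0=60, n1=50)
        ms = MomentSet(X0, X1)
        v = rng.standard_normal(6)
        exact = matvec("SqD", ms, v)
        pairs = PairStream("sampled_pairs", seed=9)
        avg = np.mean([matvec("SqD", ms, v, pairs=pairs) for _ in range(4000)], axis=0)
        np.testing.assert_allclose(avg, exact, rtol=0.1, atol=0.1 * np.abs(exact).max())

    def test_zero_vector_rejected(self):
        ms = MomentSet(np.eye(2), np.eye(2))
        with pytest.raises(ValueError, match="nonzero"):
            matvec("DS", ms, [0.0, 0.0])

    def test_unknown_method(self):
        ms = MomentSet(np.eye(2), np.eye(2))
        with pytest.raises(ValueError, match="unknown"):
            matvec("CSP", ms, [1.0, 0.0])


class TestPowerIteration:
    def test_diagonal_dominant(self):
        M = np.diag([3.0, 1.0])
        u, lam, _, conv = power_iteration(lambda v: M @ v, 2, tol=1e-12)
        assert conv
        np.testing.assert_allclose(u, [1.0, 0.0], atol=1e-5)
        assert lam == pytest.approx(3.0)

    def test_negative_dominant_shifts_to_algebraic_largest(self):
        M = np.diag([-5.0, 2.0])
        u, lam, _, conv = power_iteration(lambda v: M @ v, 2)
        assert conv
        np.testing.assert_allclose(np.abs(u), [0.0, 1.0], atol=1e-6)
        assert lam == pytest.approx(2.0, abs=1e-6)

    def test_one_dimensional(self):
        u, lam, iters, conv = power_iteration(lambda v: 7.0 * v, 1)
        assert (u[0], lam, conv) == (1.0, 7.0, True)
        assert iters == 1

    def test_degenerate_operator(self):
        with pytest.raises(DegenerateOperatorError):
            power_iteration(lambda v: 0.0 * v, 3)

    def test_sign_convention_largest_component_positive(self, rng):
        M = np.diag([4.0, 1.0])
        u, _, _, _ = power_iteration(lambda v: M @ v, 2)
        assert u[np.argmax(np.abs(u))] > 0


class TestObjectiveConsistency:
    """The quadratic forms u' M u must equal the directly computed objectives."""

    def _objectives(self, u, X0, X1):
        p0, p1 = X0 @ u, X1 @ u
        var_diff = p0.var() - p1.var()
        mean_diff_sq = (p0.mean() - p1.mean()) ** 2
        ds = (p0**2).mean() - (p1**2).mean()
        return var_diff, mean_diff_sq + var_diff, ds

    def test_var_tvm_ds_quadratic_forms(self, rng):
        for _ in range(10):
            X0, X1 = random_dataset(rng)
            ms = MomentSet(X0, X1)
            u = rng.standard_normal(X0.shape[1])
            u /= np.linalg.norm(u)
            var_obj, tvm_obj, ds_obj = self._objectives(u, X0, X1)
            assert u @ matvec("VAR", ms, u) == pytest.approx(var_obj, abs=1e-10)
            assert u @ matvec("TVM", ms, u) == pytest.approx(tvm_obj, abs=1e-10)
            assert u @ matvec("DS", ms, u) == pytest.approx(ds_obj, abs=1e-10)

    def test_dm_maximizes_mean_difference(self, rng):
        X0, X1 = random_dataset(rng, d=8)
        u, _ = estimate_single("DM", X0, X1)
        best = (X0.mean(0) - X1.mean(0)) @ u
        for _ in range(1000):
            r = rng.standard_normal(8)
            r /= np.linalg.norm(r)
            assert (X0.mean(0) - X1.mean(0)) @ r <= best + 1e-12


class TestEigenOracle:
    @pytest.mark.parametrize("method", ["VAR", "TVM", "DS", "SqD"])
    def test_power_iteration_matches_dense_eigendecomposition(self, method, rng):
        for _ in range(10):
            X0, X1 = random_dataset(rng)
            u, info = estimate_single(method, X0, X1, tol=1e-12, max_iter=20000)
            lam_dense, vec_dense = np.linalg.eigh(dense_matrix(method, X0, X1))
            assert abs(u @ vec_dense[:, -1]) >= 0.999
            assert info["eigenvalue"] == pytest.approx(lam_dense[-1], rel=1e-6)

    def test_sampled_pairs_u_close_to_independent_u(self):
        rng = np.random.default_rng(7)
        d = 10
        # strong planted direction so the pair-sampling noise stays sub-dominant
        delta = np.zeros(d)
        delta[3] = 4.0
        X1 = rng.standard_normal((400, d))
        X0 = rng.standard_normal((400, d)) + delta
        u_ind, _ = estimate_single("SqD", X0, X1)
        u_smp, _ = estimate_single(
            "SqD", X0, X1, pairing=PairStream("sampled_pairs", seed=11), max_iter=400
        )
        assert abs(u_ind @ u_smp) >= 0.99


class TestScaleEquivariance:
    @pytest.mark.parametrize("method", ["DM", "VAR", "TVM", "DS", "SqD"])
    def test_scaling_features_leaves_u_unchanged(self, method, rng):
        X0, X1 = random_dataset(rng, d=6)
        u1, _ = estimate_single(method, X0, X1, tol=1e-12, max_iter=20000)
        u2, _ = estimate_single(method, 3.7 * X0, 3.7 * X1, tol=1e-12, max_iter=20000)
        np.testing.assert_allclose(u1, u2, atol=1e-5)


def _toy_tensors(rng, n_windows=8, channels=2, samples=128, rate=64.0):
    w0 = rng.standard_normal((n_windows, channels, samples))
    w1 = rng.standard_normal((n_windows, channels, samples)) * 1.5
    return log_spectrum(w0, rate), log_spectrum(w1, rate)


TOY_BANDS = [BandDefinition("low", 1.0, 8.0), BandDefinition("high", 8.0, 30.0)]


class TestEstimateFilter:
    def test_pbf_weights_are_uniform(self, rng):
        t0, t1 = _toy_tensors(rng)
        w = estimate_filter("PBF", t0, t1, bands=TOY_BANDS)
        for key, u in w.weights.items():
            np.testing.assert_allclose(u, 1.0 / len(u))

    def test_dm_closed_form(self):
        f0 = np.array([[1.0, 5.0, 2.0]] * 4)
        f1 = np.array([[1.0, 3.0, 2.0]] * 4)
        u, _ = estimate_single("DM", f0, f1)
        np.testing.assert_allclose(u, [0.0, 1.0, 0.0])

    def test_supervised_unit_norm_and_metadata(self, rng):
        t0, t1 = _toy_tensors(rng)
        w = estimate_filter("DS", t0, t1, bands=TOY_BANDS)
        for key, u in w.weights.items():
            assert np.linalg.norm(u) == pytest.approx(1.0)
            assert w.info[key]["converged"]

    def test_joint_scope_spans_channels(self, rng):
        t0, t1 = _toy_tensors(rng)
        w = estimate_filter("DM", t0, t1, bands=TOY_BANDS, scope="joint")
        sizes = {b: (s[1] - s[0]) for b, s in w.band_ranges.items()}
        for band in w.band_names:
            assert len(w.weights[f"joint:{band}"]) == 2 * sizes[band]
        assert w.n_columns == len(TOY_BANDS)

    def test_json_roundtrip(self, rng, tmp_path):
        t0, t1 = _toy_tensors(rng)
        w = estimate_filter("TVM", t0, t1, bands=TOY_BANDS)
        w.to_json(tmp_path / "w.json")
        back = FilterWeights.from_json(tmp_path / "w.json")
        assert back.method == "TVM"
        for key in w.weights:
            np.testing.assert_allclose(back.weights[key], w.weights[key])


class TestApplyFilters:
    def test_pbf_on_ones_gives_ones(self, rng):
        t0, t1 = _toy_tensors(rng)
        w = estimate_filter("PBF", t0, t1, bands=TOY_BANDS)
        ones = SpectralTensor(
            values=np.ones_like(t0.values),
            freq_hz=t0.freq_hz,
            window_starts_sec=t0.window_starts_sec,
            sampling_rate_hz=t0.sampling_rate_hz,
            fft_length=t0.fft_length,
        )
        np.testing.assert_allclose(apply_filters(ones, w), 1.0)

    def test_column_count_is_channels_times_bands(self):
        clip = make_clip(duration=60.0, rate=400.0, channels=16, kind="preictal")
        from preictal.spectral import clip_spectrum

        t = clip_spectrum(clip)
        w = estimate_filter("PBF", [t, t], [t, t])
        assert apply_filters(t, w).shape == (1, 96)  # 16 channels x 6 bands

    def test_zero_spectrum_gives_zero_features(self, rng):
        t0, t1 = _toy_tensors(rng)
        w = estimate_filter("PBF", t0, t1, bands=TOY_BANDS)
        zeros = SpectralTensor(
            values=np.zeros_like(t0.values),
            freq_hz=t0.freq_hz,
            window_starts_sec=t0.window_starts_sec,
            sampling_rate_hz=t0.sampling_rate_hz,
            fft_length=t0.fft_length,
        )
        np.testing.assert_array_equal(apply_filters(zeros, w), 0.0)

    def test_geometry_mismatch_rejected(self, rng):
        t0, t1 = _toy_tensors(rng)
        w = estimate_filter("PBF", t0, t1, bands=TOY_BANDS)
        other = log_spectrum(rng.standard_normal((2, 2, 64)), 64.0)
        with pytest.raises(ValueError, match="geometry"):
            apply_filters(other, w)

    def test_log_order_post_applies_log_after_filtering(self, rng):
        raw0 = log_spectrum(rng.standard_normal((6, 2, 128)), 64.0, log_order="post")
        raw1 = log_spectrum(rng.standard_normal((6, 2, 128)) * 2, 64.0, log_order="post")
        w = estimate_filter("PBF", raw0, raw1, bands=TOY_BANDS)
        feats = apply_filters(raw0, w)
        start, stop = w.band_ranges["low"]
        expected = np.log1p(raw0.values[:, 0, start:stop].mean(axis=1))
        np.testing.assert_allclose(feats[:, 0], expected, rtol=1e-12)
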