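"""Fusion core: weights, multi-source combination, features, baselines."""

import numpy as np
import pytest

import teamfuse as tf
from teamfuse.errors import FusionError, ValidationError
from teamfuse.fuse import WeightState, update_weight


class TestWeightRecursion:
    def test_single_update_table2_lambda(self):
        state = WeightState(w={"s": 0.5}, lambda_=0.65)
        out = update_weight(state, {"s": 1.0}, {"s": 1.0})
        assert out.w["s"] == pytest.approx(0.65 * 0.5 + 0.35 * 1.0)  # 0.675

    def test_lambda_zero_jumps_to_qr(self):
        state = WeightState(w={"s": 0.9}, lambda_=0.0)
        out = update_weight(state, {"s": 0.4}, {"s": 0.5})
        assert out.w["s"] == pytest.approx(0.2)

    def test_geometric_convergence_random_instances(self):
        rng = np.random.default_rng(0)
        lam = 0.65
        for _ in range(50):
            w0, c = rng.random(), rng.random()
            state = WeightState(w={"s": w0}, lambda_=lam)
            for t in range(1, 15):
                state = update_weight(state, {"s": c}, {"s": 1.0})
                assert abs(state.w["s"] - c) == pytest.approx(
                    lam ** t * abs(w0 - c), abs=1e-12)

    def test_normalization_sums_to_one(self):
        state = WeightState(w={"a": 0.2, "b": 0.7}, lambda_=0.65)
        assert sum(state.normalized().values()) == pytest.approx(1.0)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValidationError):
            WeightState(w={"s": 0.5}, lambda_=1.5)


def _positional_stream(sensor, modality, t, xy, vxy, sigma_nominal):
    vals = np.column_stack([xy, vxy])
    return tf.SensorStream("A1", sensor, modality,
                           ["x_m", "y_m", "vx_mps", "vy_mps"], t, vals,
                           units=["m", "m", "m/s", "m/s"],
                           nominal_accuracy=[sigma_nominal] * 2 + [0.05] * 2)


class TestFuseIndividual:
    def test_single_noiseless_source_is_identity(self):
        t = np.arange(0, 30, 0.025)
        xy = np.column_stack([np.sin(0.5 * t), np.cos(0.5 * t)])
        vxy = np.column_stack([0.5 * np.cos(0.5 * t), -0.5 * np.sin(0.5 * t)])
        s = _positional_stream("A1-lps", "lps", t, xy, vxy, 0.1)
        rec = tf.fuse_individual([s])
        truth = np.column_stack([np.sin(0.5 * rec.t), np.cos(0.5 * rec.t)])
        assert np.sqrt(np.mean((rec.position - truth) ** 2)) < 1e-6

    def test_two_source_combination_near_inverse_variance_optimum(self):
        """sigma = (0.1, 0.5) unbiased sources: fused RMSE within 5% of the
        inverse-variance bound sigma_opt ~ 0.098."""
        rng = np.random.default_rng(8)
        t = np.arange(0, 500, 0.05)
        truth = np.column_stack([np.sin(0.25 * t), np.cos(0.25 * t)])
        v = np.zeros_like(truth)
        streams = []
        for name, mod, sig in (("A1-lps", "lps", 0.1), ("A1-gps", "gps", 0.5)):
            noisy = truth + sig * rng.standard_normal(truth.shape)
            streams.append(_positional_stream(name, mod, t, noisy, v, sig))
        rec = tf.fuse_individual(streams)
        ref = np.column_stack([np.sin(0.25 * rec.t), np.cos(0.25 * rec.t)])
        rmse = np.sqrt(np.mean((rec.position - ref) ** 2))
        assert rmse < 0.1 * 1.05

    def test_degraded_source_weight_decays_monotonically(self):
        """30% amplitude noise injected mid-session drags that source's
        weight down over the following updates."""
        rng = np.random.default_rng(3)
        t = np.arange(0, 60, 0.05)
        truth = np.column_stack([np.sin(0.25 * t), np.cos(0.25 * t)])
        v = np.zeros_like(truth)
        lps = _positional_stream("A1-lps", "lps", t, truth + 0.05 *
                                 rng.standard_normal(truth.shape), v, 0.1)
        gps_vals = truth + 0.05 * rng.standard_normal(truth.shape)
        half = t.size // 2
        gps_vals[half:] += 0.6 * rng.standard_normal((t.size - half, 2))
        gps = _positional_stream("A1-gps", "gps", t, gps_vals, v, 0.5)
        rec = tf.fuse_individual([lps, gps], weight_block_s=2.0)
        w = rec.weight_history["gps:raw"]
        bt = rec.weight_history["block_t"]
        after = w[bt > 30.0][:10]
        # geometric decay dominates until the weight reaches the quality
        # floor; the drop itself is an order of magnitude
        assert np.all(np.diff(after[:7]) < 0)
        assert after[-1] < w[bt < 30.0].mean() / 4
        applied = rec.weight_history["gps"]
        assert applied[bt > 32.0].max() < 0.1 * applied[bt < 30.0].mean()

    def test_no_positional_source_rejected(self):
        t = np.arange(0, 10, 0.1)
        physio = tf.SensorStream("A1", "A1-ph", "physio", ["hr_bpm"], t,
                                 60 + np.zeros((t.size, 1)))
        with pytest.raises(FusionError, match="positional"):
            tf.fuse_individual([physio])


class TestFuseTeam:
    @staticmethod
    def _rec(aid, offset):
        t = np.arange(0, 10, 0.05)
        pos = np.full((t.size, 2), float(offset))
        z = np.zeros((t.size, 2))
        return tf.AlignedAthleteRecord(aid, t, pos, z, z,
                                       np.zeros((t.size, 3)),
                                       np.zeros(t.size), np.zeros(t.size))

    def test_centroid_is_mean(self):
        team = tf.fuse_team([self._rec("A1", 0), self._rec("A2", 2)])
        assert np.allclose(team.centroid, 1.0, atol=1e-12)

    def test_permutation_invariance(self):
        recs = [self._rec(a, k) for k, a in enumerate(["A1", "A2", "A3"])]
        c1 = tf.fuse_team(recs).centroid
        c2 = tf.fuse_team(recs[::-1]).centroid
        assert np.allclose(c1, c2, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a, b = self._rec("A1", 0), self._rec("A2", 1)
        b.t = b.t + 0.013
        with pytest.raises(FusionError):
            tf.fuse_team([a, b])


class TestWaveletPacket:
    def test_perfect_reconstruction_and_parseval(self, rng):
        for _ in range(10):
            x = rng.standard_normal(256)
            feats = tf.wavelet_packet(x, level=5)
            assert np.linalg.norm(feats.reconstruct() - x) / \
                np.linalg.norm(x) < 1e-8
            assert feats.total_energy() == pytest.approx(
                float((x ** 2).sum()), rel=1e-8)

    def test_constant_signal_energy_in_lowpass_node(self):
        feats = tf.wavelet_packet(np.full(64, 2.0), level=3)
        energies = feats.leaf_energies()
        low = energies.pop("aaa")
        assert low == pytest.approx(64 * 4.0, rel=1e-8)
        assert all(e < 1e-16 * low for e in energies.values())

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValidationError, match="2\\^5"):
            tf.wavelet_packet(np.zeros(16), level=5)


class TestFeatureSelection:
    def test_full_retention_zero_error(self, rng):
        feats = tf.wavelet_packet(rng.standard_normal(128), level=4)
        red = tf.select_features(feats, alpha_feat=1.0)
        assert red.reconstruction_error < 1e-10

    def test_three_tone_energy_capture(self):
        t = np.arange(1024) / 256.0
        x = (np.sin(2 * np.pi * 3 * t) + 0.7 * np.sin(2 * np.pi * 11 * t)
             + 0.5 * np.sin(2 * np.pi * 29 * t))
        red = tf.select_features(tf.wavelet_packet(x, level=5), alpha_feat=0.15)
        assert red.retained_energy_fraction >= 0.94

    def test_error_monotone_in_alpha(self, rng):
        feats = tf.wavelet_packet(rng.standard_normal(256), level=5)
        errs = [tf.select_features(feats, a).reconstruction_error
                for a in (0.05, 0.15, 0.4, 0.8, 1.0)]
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errs, errs[1:]))


class TestTensorFuse:
    def test_identity_projections(self, rng):
        X = rng.standard_normal((2, 3, 4))
        out = tf.tensor_fuse(X, np.eye(2), np.eye(3), np.eye(4))
        assert np.array_equal(out.result, X)

    def test_equals_triple_sum_oracle_and_order_invariance(self, rng):
        X = rng.standard_normal((2, 3, 4))
        W1 = rng.standard_normal((5, 2))
        W2 = rng.standard_normal((2, 3))
        W3 = rng.standard_normal((3, 4))
        out = tf.tensor_fuse(X, W1, W2, W3).result
        naive = np.zeros((5, 2, 3))
        for a in range(5):
            for b in range(2):
                for c in range(3):
                    for i in range(2):
                        for j in range(3):
                            for k in range(4):
                                naive[a, b, c] += X[i, j, k] * W1[a, i] * \
                                    W2[b, j] * W3[c, k]
        assert np.abs(out - naive).max() < 1e-12
        other = np.einsum("ijk,bj->ibk", X, W2)
        other = np.einsum("ibk,ai->abk", other, W1)
        other = np.einsum("abk,ck->abc", other, W3)
        assert np.abs(out - other).max() < 1e-12

    def test_dimension_mismatch_names_mode(self, rng):
        X = rng.standard_normal((2, 3, 4))
        with pytest.raises(ValidationError, match="mode 2"):
            tf.tensor_fuse(X, np.eye(2), np.eye(4), np.eye(4))


class TestQInfo:
    def test_identity_preserves_information(self, rng):
        x = rng.standard_normal(10_000)
        assert tf.q_info(x, x).q_info >= 0.99

    def test_independent_output_near_zero(self, rng):
        x = rng.standard_normal(10_000)
        f = np.random.default_rng(999).standard_normal(10_000)
        assert tf.q_info(x, f).q_info <= 0.05

    def test_monotone_decreasing_in_noise(self, rng):
        x = rng.standard_normal(20_000)
        vals = []
        for sigma in (0.1, 0.3, 1.0, 3.0, 10.0):
            f = x + sigma * rng.standard_normal(x.size)
            vals.append(tf.q_info(x, f).q_info)
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0 <= v <= 1 for v in vals)

    def test_constant_input_flagged(self):
        rep = tf.q_info(np.ones(200), np.arange(200.0))
        assert rep.q_info is None and rep.flags


class TestBaselineFusers:
    def test_kalman_gain_limits(self):
        z = np.array([[2.0], [2.0], [2.0]])
        near = tf.kalman_fuse(z, [[1.0]], [[0.0]], [[1e-12]], [0.0], [[1.0]])
        assert near[-1, 0] == pytest.approx(2.0, abs=1e-6)
        far = tf.kalman_fuse(z, [[1.0]], [[0.0]], [[1e12]], [0.5], [[1e-12]])
        assert far[-1, 0] == pytest.approx(0.5, abs=1e-6)

    def test_static_fusion_matches_conjugate_gaussian_and_bayes(self):
        z1, z2, s1, s2 = 1.0, 2.0, 0.1, 0.2
        p0 = 4.0
        kal = tf.kalman_fuse(np.array([[z1, z2]]), H=[[1.0], [1.0]],
                             Q_proc=[[0.0]], R_meas=np.diag([s1 ** 2, s2 ** 2]),
                             x0=[0.0], P0=[[p0]])
        prec = 1 / p0 + 1 / s1 ** 2 + 1 / s2 ** 2
        closed = (z1 / s1 ** 2 + z2 / s2 ** 2) / prec
        assert kal[-1, 0] == pytest.approx(closed, abs=1e-12)
        bm, bv = tf.bayes_fuse(0.0, p0, np.array([[z1], [z2]]),
                               np.array([[s1 ** 2], [s2 ** 2]]))
        assert bm[0] == pytest.approx(kal[-1, 0], abs=1e-12)
        assert bv[0] == pytest.approx(1 / prec, abs=1e-12)

    def test_weighted_average_identity_and_validation(self):
        x = np.arange(5.0)
        assert np.array_equal(tf.weighted_average_fuse([x, x], [0.5, 0.5]), x)
        with pytest.raises(ValidationError):
            tf.weighted_average_fuse([x, x], [-0.5, 1.5])

    def test_bayes_flat_prior_single_source(self):
        bm, _ = tf.bayes_fuse(0.0, np.inf, np.array([[3.3]]), np.array([[0.04]]))
        assert bm[0] == pytest.approx(3.3)


class TestCompareFusers:
    def test_zero_noise_all_fusers_near_exact(self, clean_session):
        manifest, streams, truth = clean_session
        table = tf.compare_fusers(manifest, streams, truth,
                                  fusers=("multilevel", "wavg", "bayes",
                                          "gps_only"))
        assert (table["position_rmse_m"] < 1e-4).all()
        row = table.set_index("fuser")
        assert row.loc["multilevel", "position_rmse_m"] < 1e-6

    def test_multilevel_beats_gps_under_nominal_noise(self, small_session):
        manifest, streams, truth = small_session
        table = tf.compare_fusers(manifest, streams, truth,
                                  fusers=("multilevel", "gps_only")
                                  ).set_index("fuser")
        assert table.loc["multilevel", "position_rmse_m"] < \
            table.loc["gps_only", "position_rmse_m"]
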