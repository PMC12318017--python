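"""Indicator system: entropies, RPM, CRQA, phase synchrony, windowed battery."""

import numpy as np
import pandas as pd
import pytest

import teamfuse as tf
from teamfuse.errors import ValidationError
from teamfuse.indicators import (IndicatorConfig, ZoneGrid, crqa_from_matrix,
                                 movement_phases, perturbation_recovery,
                                 team_subset)


def _grid(p, nx=2, ny=2, normalization="joint"):
    return ZoneGrid(n_x=nx, n_y=ny, pitch_extent=(-1, 1, -1, 1),
                    occupancy=np.asarray(p, float), normalization=normalization)


class TestSpatialEntropy:
    def test_uniform_occupancy_log_cells(self):
        assert tf.spatial_entropy(_grid(np.full((1, 4), 0.25))) == \
            pytest.approx(2.0)

    def test_degenerate_occupancy_zero(self):
        p = np.zeros((1, 4))
        p[0, 2] = 1.0
        assert tf.spatial_entropy(_grid(p)) == 0.0

    def test_hand_summed_distribution(self):
        p = np.array([[0.5, 0.25], [0.125, 0.125]])
        assert tf.spatial_entropy(_grid(p)) == pytest.approx(1.75)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError, match="normalized"):
            tf.spatial_entropy(_grid(np.full((1, 4), 0.3)))

    def test_occupancy_from_trajectory_bounds(self, small_session):
        _, _, truth = small_session
        g = tf.occupancy_grid(truth.team, 6, 4, (-20, 20, -15, 15))
        s = tf.spatial_entropy(g)
        assert 0 <= s <= np.log2(24)


class TestRPM:
    def test_identical_series_one(self, rng):
        d = rng.random((50, 3)) + 1
        val, flags = tf.rpm(d, d)
        assert val == pytest.approx(1.0)

    def test_anticorrelated_minus_one(self, rng):
        d = rng.random((50, 2)) + 1
        val, _ = tf.rpm(d, -d + 5.0)
        assert val == pytest.approx(-1.0)

    def test_equals_mean_pearson_oracle(self, rng):
        d = rng.random((100, 4))
        ref = rng.random((100, 4))
        val, _ = tf.rpm(d, ref)
        oracle = np.mean([np.corrcoef(d[:, j], ref[:, j])[0, 1]
                          for j in range(4)])
        assert val == pytest.approx(oracle, abs=1e-12)

    def test_constant_reference_fallback_flagged(self, rng):
        d = np.abs(rng.random((50, 1))) + 2.0
        ref = np.full((50, 1), float(d.mean()))
        val, flags = tf.rpm(d, ref)
        assert any("fallback" in f for f in flags)
        expected = 1 - np.abs(d[:, 0] - ref[:, 0]).mean() / ref[0, 0]
        assert val == pytest.approx(expected)

    def test_all_excluded_undefined(self):
        d = np.ones((10, 2))
        val, flags = tf.rpm(d, d)
        assert np.isnan(val) and any("undefined" in f for f in flags)


class TestCRQA:
    def test_self_recurrence_diagonal(self, rng):
        X = rng.standard_normal((12, 2))
        res = tf.cross_recurrence(X, X, epsilon=1e-9)
        assert np.all(np.diag(res.CR) == 1)

    def test_epsilon_above_max_distance_all_ones(self, rng):
        X = rng.standard_normal((10, 2))
        Y = rng.standard_normal((10, 2))
        eps = float(np.linalg.norm(X[:, None] - Y[None, :], axis=2).max()) + 1
        res = tf.cross_recurrence(X, Y, epsilon=eps)
        assert res.RR == 1.0
        # every point lies on a long diagonal except the two corner cells,
        # whose diagonals have length 1 < l_min
        assert res.DET == pytest.approx((100 - 2) / 100)
        assert res.LAM == 1.0

    def test_hand_counted_matrix(self):
        """Two length-3 diagonals + 2 singletons; l_min=2 => DET = 6/8."""
        CR = np.zeros((8, 8), dtype=int)
        for k in range(3):
            CR[k, k] = 1            # diagonal of length 3
            CR[4 + k, 3 + k] = 1    # second diagonal of length 3
        CR[0, 7] = 1                # singletons
        CR[7, 0] = 1
        res = crqa_from_matrix(CR, l_min=2)
        assert res.RR == pytest.approx(8 / 64)
        assert res.DET == pytest.approx(6 / 8)
        assert res.ENT_diag == pytest.approx(0.0)   # both kept lines length 3
        CR[3, 3] = CR[4, 4] = 1     # extend: lengths now {5, 3}
        res2 = crqa_from_matrix(CR, l_min=2)
        assert res2.ENT_diag == pytest.approx(1.0)  # two equally likely lengths

    def test_rr_equals_brute_force_counting(self, rng):
        for _ in range(5):
            X = rng.standard_normal((15, 3))
            Y = rng.standard_normal((18, 3))
            eps = 1.5
            res = tf.cross_recurrence(X, Y, epsilon=eps)
            brute = np.mean([[np.linalg.norm(xi - yj) <= eps for yj in Y]
                             for xi in X])
            assert res.RR == pytest.approx(brute)

    def test_multiscale_coarse_graining_shrinks_matrix(self, rng):
        X = rng.standard_normal((40, 2))
        out = tf.ms_crqa(X, X, epsilon=1.0, scales=(1, 2, 4))
        assert out[1].CR.shape == (40, 40)
        assert out[2].CR.shape == (20, 20)
        assert out[4].CR.shape == (10, 10)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValidationError):
            tf.cross_recurrence(np.zeros((5, 1)), np.zeros((5, 1)), epsilon=0.0)


class TestPhaseMachinery:
    def test_tone_phase_slope(self):
        t = np.arange(0, 10, 0.01)
        ps = tf.hilbert_phase(np.cos(2 * np.pi * 1.0 * t), 100.0)
        trim = int(0.05 * t.size)
        slope = np.polyfit(t[trim:-trim], ps.phases[trim:-trim, 0], 1)[0]
        assert slope == pytest.approx(2 * np.pi, rel=0.01)

    def test_identical_sinusoids_full_synchrony(self):
        t = np.arange(0, 10, 0.01)
        x = np.column_stack([np.sin(2 * np.pi * t)] * 5)
        R = tf.hilbert_phase(x, 100.0).order_parameter()
        assert np.allclose(R, 1.0, atol=1e-9)

    def test_antiphase_pair_cancels(self):
        t = np.arange(0, 10, 0.01)
        x = np.column_stack([np.sin(2 * np.pi * t), -np.sin(2 * np.pi * t)])
        R = tf.hilbert_phase(x, 100.0).order_parameter()
        trim = int(0.05 * t.size)
        assert R[trim:-trim].max() <= 0.02

    def test_uniform_phases_near_zero(self, rng):
        phases = rng.uniform(0, 2 * np.pi, (1, 10_000))
        assert tf.order_parameter(phases)[0] == pytest.approx(0.0, abs=0.02)

    def test_zero_signal_flagged_undefined(self):
        ps = tf.hilbert_phase(np.zeros(100), 10.0)
        assert ps.undefined


class TestGini:
    def test_equal_loads_zero(self):
        assert tf.gini(np.full(7, 3.0)) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_single_carrier_closed_form(self, n):
        x = np.zeros(n)
        x[0] = 10.0
        assert tf.gini(x) == pytest.approx((n - 1) / n)


def _synthetic_team(n=4, dur=60.0, rate=20.0, seed=0, shared_velocity=False):
    rng = np.random.default_rng(seed)
    t = np.arange(0, dur, 1 / rate)
    pos = np.zeros((t.size, n, 2))
    vel = np.zeros((t.size, n, 2))
    for k in range(n):
        phase = 0.0 if shared_velocity else rng.uniform(0, 2 * np.pi)
        pos[:, k, 0] = 3 * np.cos(2 * np.pi * 0.25 * t + phase) + 5 * k
        pos[:, k, 1] = 3 * np.sin(2 * np.pi * 0.25 * t + phase)
        vel[:, k, 0] = -3 * 2 * np.pi * 0.25 * np.sin(2 * np.pi * 0.25 * t + phase)
        vel[:, k, 1] = 3 * 2 * np.pi * 0.25 * np.cos(2 * np.pi * 0.25 * t + phase)
    ids = [f"A{k+1}" for k in range(n)]
    return tf.TeamTrajectory(t=t, athlete_ids=ids, positions=pos,
                             velocities=vel, team_of={i: "A" for i in ids})


class TestIndicatorBattery:
    def test_shared_motion_gives_unit_ssi_icc(self):
        team = _synthetic_team(shared_velocity=True)
        out = tf.compute_indicators(team, config=IndicatorConfig(
            pitch_extent=(-30, 30, -30, 30)))
        assert np.nanmean(out.table["SSI"]) == pytest.approx(1.0, abs=1e-6)
        assert np.nanmean(out.table["ICC"]) == pytest.approx(1.0, abs=1e-6)

    def test_ssi_invariant_to_translation_and_rotation(self):
        team = _synthetic_team(seed=4)
        base = tf.compute_indicators(team, config=IndicatorConfig(
            pitch_extent=(-30, 30, -30, 30)))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = tf.TeamTrajectory(
            t=team.t, athlete_ids=team.athlete_ids,
            positions=team.positions @ R.T + np.array([3.0, -2.0]),
            velocities=team.velocities @ R.T, team_of=team.team_of)
        out = tf.compute_indicators(moved, config=IndicatorConfig(
            pitch_extent=(-40, 40, -40, 40)))
        assert np.allclose(out.table["SSI"], base.table["SSI"], atol=1e-9)

    def test_tie_entropy_extremes(self):
        team = _synthetic_team(n=3)
        uniform_rows = []
        for i in range(3):
            for j in range(3):
                if i != j:
                    uniform_rows.append({"t": 1.0 + 0.1 * len(uniform_rows),
                                         "event_type": "pass",
                                         "athlete_id": f"A{i+1}",
                                         "target_athlete_id": f"A{j+1}",
                                         "outcome": "complete"})
        ev = tf.EventTable(pd.DataFrame(uniform_rows))
        cfg = IndicatorConfig(window_s=10.0, pitch_extent=(-30, 30, -30, 30))
        out = tf.compute_indicators(team, ev, config=cfg)
        assert out.table["TIE"].iloc[0] == pytest.approx(1.0)
        one_pair = tf.EventTable(pd.DataFrame(
            [{"t": 1.0 + 0.1 * k, "event_type": "pass", "athlete_id": "A1",
              "target_athlete_id": "A2", "outcome": "complete"}
             for k in range(6)]))
        out2 = tf.compute_indicators(team, one_pair, config=cfg)
        assert out2.table["TIE"].iloc[0] == pytest.approx(0.0)

    def test_missing_events_flagged_nan_not_zero(self):
        team = _synthetic_team()
        out = tf.compute_indicators(team, tf.EventTable(), config=IndicatorConfig(
            pitch_extent=(-30, 30, -30, 30)))
        assert out.table["TIE"].isna().all()
        assert out.table["DMS"].isna().all()

    def test_equal_loads_full_harmony(self):
        team = _synthetic_team(shared_velocity=True)
        out = tf.compute_indicators(team, config=IndicatorConfig(
            pitch_extent=(-30, 30, -30, 30)))
        assert np.allclose(out.table["LDH"], 1.0, atol=1e-6)

    def test_cpr_recovers_constructed_step(self):
        """SSI dips at t=100 s and recovers at t=130 s: CPR ~ 30 s."""
        t_windows = np.arange(5.0, 200.0, 5.0)
        ssi = np.full(t_windows.size, 0.9)
        dip = (t_windows >= 100) & (t_windows < 130)
        ssi[dip] = 0.2
        rng = np.random.default_rng(0)
        ssi += 0.01 * rng.standard_normal(ssi.size)
        rec = perturbation_recovery(t_windows, ssi, 100.0)
        assert rec == pytest.approx(30.0, abs=5.0)

    def test_r_mean_tracks_generative_synchrony(self, small_session):
        _, _, truth = small_session
        sub = team_subset(truth.team, "A")
        ph = movement_phases(sub)
        R = tf.order_parameter(ph.phases)
        gen = tf.order_parameter(truth.phases[:, :2])
        n = R.size
        assert abs(R[n//10:-n//10].mean() - gen[n//10:-n//10].mean()) < 0.25
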