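"""Migration statistics against hand computations and independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flowtaxis.metrics import (ArrestRule, DirectionRule, Window,
                               arrest_coefficient, arrest_rule_from_static,
                               confinement_ratio, displacement,
                               ensemble_speed_timeseries, frame_speeds,
                               motility_coefficient, net_direction_class,
                               path_length, rms_displacement_curve,
                               summarize_group, time_direction_fractions)
from flowtaxis.simulate import SimParams, simulate_trackset
from flowtaxis.tracks import Track, TrackSet

from conftest import straight_track, track_from_steps


def naive_rms_curve(trackset):
    """Independent double-loop implementation of the ensemble RMS displacement."""
    T = trackset.tracks[0].n_frames
    out = np.zeros(T)
    for k in range(T):
        acc = 0.0
        for tr in trackset.tracks:
            dx = tr.xy[k, 0] - tr.xy[0, 0]
            dy = tr.xy[k, 1] - tr.xy[0, 1]
            acc += dx * dx + dy * dy
        out[k] = math.sqrt(acc / trackset.n)
    return out


# ---------------------------------------------------------------- speeds

def test_frame_speeds_hand_values():
    assert np.all(frame_speeds(straight_track(5, (0.0, 0.0))) == 0.0)
    assert np.all(frame_speeds(straight_track(5, (1.0, 0.0))) == 1.0)
    assert frame_speeds(straight_track(5, (3.0, 4.0))) == pytest.approx([5.0] * 5)


def test_frame_speeds_requires_uniform_time_base():
    tr = straight_track(5)
    with pytest.raises(ValueError, match="dt"):
        frame_speeds(tr, dt=2.0)


def test_ensemble_speed_mean_and_sem():
    ts = TrackSet("g", [straight_track(4, (1.0, 0.0), cell_id=0),
                        straight_track(4, (3.0, 0.0), cell_id=1)], dt=1.0)
    out = ensemble_speed_timeseries(ts)
    assert np.all(out["mean_speed_um_min"] == 2.0)
    assert np.all(out["sem_um_min"] == 1.0)
    single = ensemble_speed_timeseries(TrackSet("g", [straight_track(4)], dt=1.0))
    assert np.all(single["sem_um_min"] == 0.0)


# ------------------------------------------------- displacement and paths

def test_displacement_and_path_cases():
    straight = straight_track(10)
    assert displacement(straight) == pytest.approx(10.0)
    assert path_length(straight) == pytest.approx(10.0)
    assert confinement_ratio(straight) == pytest.approx(1.0)

    steps = [(1.0, 0.0)] * 5 + [(-1.0, 0.0)] * 5
    out_and_back = track_from_steps(steps)
    assert displacement(out_and_back) == pytest.approx(0.0)
    assert path_length(out_and_back) == pytest.approx(10.0)
    assert confinement_ratio(out_and_back) == pytest.approx(0.0)

    l_path = track_from_steps([(3.0, 0.0), (0.0, 4.0)])
    assert displacement(l_path) == pytest.approx(5.0)
    assert path_length(l_path) == pytest.approx(7.0)
    assert confinement_ratio(l_path) == pytest.approx(5.0 / 7.0)

    stationary = straight_track(5, (0.0, 0.0))
    assert confinement_ratio(stationary) == 0.0  # 0/0 convention


def test_window_outside_track_raises():
    tr = straight_track(10)
    with pytest.raises(ValueError, match="not\\s+covered|covered"):
        displacement(tr, Window(0, 30))


# ---------------------------------------------------------------- arrest

def test_arrest_rule_pooled_hand_computation():
    """Pooled speeds {0.1, 0.2, 0.3}: mean 0.2, population SD 0.0816."""
    tr = track_from_steps([(0.1, 0.0), (0.2, 0.0), (0.3, 0.0)])
    rule = arrest_rule_from_static(TrackSet("static", [tr], dt=1.0))
    assert rule.static_mean == pytest.approx(0.2)
    assert rule.static_sd == pytest.approx(0.081650, abs=1e-6)
    assert rule.threshold == pytest.approx(0.118350, abs=1e-6)


def test_arrest_rule_zero_spread():
    tr = straight_track(5, (0.4, 0.0))
    rule = arrest_rule_from_static(TrackSet("static", [tr], dt=1.0))
    assert rule.threshold == pytest.approx(0.4)


def test_arrest_rule_nonpositive_threshold_rejected():
    tr = track_from_steps([(0.0, 0.0), (1.0, 0.0)])  # mean 0.5, sd 0.5
    with pytest.raises(ValueError, match="threshold"):
        arrest_rule_from_static(TrackSet("static", [tr], dt=1.0))


def test_arrest_coefficient_strict_threshold():
    tr = track_from_steps([(0.1, 0), (0.3, 0), (0.1, 0), (0.3, 0)])
    rule = ArrestRule.from_mean_sd(0.21, 0.05)
    assert arrest_coefficient(tr, rule) == pytest.approx(0.5)
    fast = straight_track(4, (0.5, 0.0))
    assert arrest_coefficient(fast, rule) == 0.0
    boundary = straight_track(4, (rule.threshold, 0.0))
    assert arrest_coefficient(boundary, rule) == 0.0  # speeds == threshold move


def test_arrest_converges_to_stationary_paused_fraction(two_state_params):
    """Markov-chain oracle: mean arrest -> p_pause / (p_pause + p_resume)."""
    ts = simulate_trackset(two_state_params, np.random.default_rng(8))
    rule = ArrestRule.from_mean_sd(0.30, 0.05)  # 0.25, between pause and base speed
    vals = [arrest_coefficient(tr, rule) for tr in ts.tracks]
    expected = two_state_params.stationary_paused_fraction()
    assert np.mean(vals) == pytest.approx(expected, abs=0.02)


# ------------------------------------------------------------- direction

def test_net_direction_classification():
    rule = DirectionRule(flow_angle=0.0)
    east = straight_track(5, (2.0, 0.0))
    west = straight_track(5, (-2.0, 0.0))
    north = straight_track(5, (0.0, 2.0))
    assert net_direction_class(east, rule) == "with"
    assert net_direction_class(west, rule) == "against"
    assert net_direction_class(north, rule) == "neither"
    # inclusive boundary at exactly pi/8
    boundary = straight_track(5, (math.cos(math.pi / 8), math.sin(math.pi / 8)))
    assert net_direction_class(boundary, rule) == "with"
    stationary = straight_track(5, (0.0, 0.0))
    assert net_direction_class(stationary, rule) == "neither"


def test_time_direction_fractions():
    rule = DirectionRule()
    east = straight_track(6, (1.0, 0.0))
    assert time_direction_fractions(east, rule) == (1.0, 0.0)
    alternating = track_from_steps([(1.0, 0.0), (-1.0, 0.0)] * 3)
    assert time_direction_fractions(alternating, rule) == (0.5, 0.5)
    # zero-length steps are neither
    with_pause = track_from_steps([(1.0, 0.0), (0.0, 0.0), (1.0, 0.0)])
    fw, fa = time_direction_fractions(with_pause, rule)
    assert (fw, fa) == (pytest.approx(2 / 3), 0.0)


def test_isotropic_step_fractions_match_arc():
    params = SimParams(n_cells=400, n_frames=61, base_speed=0.5, speed_sd=0.1,
                       persistence_sigma=10.0, p_pause=0.0, p_resume=1.0)
    ts = simulate_trackset(params, np.random.default_rng(12))
    rule = DirectionRule()
    fr = np.array([time_direction_fractions(tr, rule) for tr in ts.tracks])
    n_steps = 400 * 60
    tol = 4 * math.sqrt(0.125 * 0.875 / n_steps)
    assert fr[:, 0].mean() == pytest.approx(0.125, abs=tol)
    assert fr[:, 1].mean() == pytest.approx(0.125, abs=tol)


# ------------------------------------------------------------------ RMS

def test_rms_hand_values():
    ts = TrackSet("g", [track_from_steps([(3.0, 0.0)], cell_id=0),
                        track_from_steps([(0.0, 4.0)], cell_id=1)], dt=1.0)
    curve = rms_displacement_curve(ts)
    assert curve.rms[0] == 0.0
    assert curve.rms[1] == pytest.approx(math.sqrt((9 + 16) / 2))
    same = TrackSet("g", [straight_track(3, (5.0, 0.0), cell_id=i)
                          for i in range(4)], dt=1.0)
    assert rms_displacement_curve(same).rms[1] == pytest.approx(5.0)


def test_rms_requires_equal_length_tracks():
    ts = TrackSet("g", [straight_track(5, cell_id=0),
                        straight_track(3, cell_id=1)], dt=1.0)
    with pytest.raises(ValueError, match="unequal"):
        rms_displacement_curve(ts)


def test_rms_matches_naive_oracle(small_trackset):
    curve = rms_displacement_curve(small_trackset)
    oracle = naive_rms_curve(small_trackset)
    np.testing.assert_allclose(curve.rms, oracle, rtol=1e-12, atol=1e-12)


# ------------------------------------------------------------- motility

def test_motility_fit_exact_sqrt_curve():
    t = np.arange(0, 31, dtype=float)
    ts = TrackSet("g", [Track(i, t, np.column_stack([2 * np.sqrt(t), 0 * t]))
                        for i in range(2)], dt=1.0)
    fit = motility_coefficient(rms_displacement_curve(ts))
    assert fit.slope == pytest.approx(2.0, abs=1e-9)
    assert fit.intercept == pytest.approx(0.0, abs=1e-9)


def test_motility_fit_plateau_and_options():
    t = np.arange(0, 21, dtype=float)
    rms = np.full_like(t, 7.0)
    rms[0] = 0.0
    from flowtaxis.metrics import EnsembleCurve
    curve = EnsembleCurve(t, rms, n_cells=3)
    fit = motility_coefficient(curve, Window(1, 20), include_t0=False)
    assert fit.slope == pytest.approx(0.0, abs=1e-9)
    origin_fit = motility_coefficient(curve, through_origin=True)
    assert origin_fit.intercept == 0.0
    with pytest.raises(ValueError, match=">= 3"):
        motility_coefficient(EnsembleCurve(t[:2], rms[:2] * 0, 1))


# ----------------------------------------------------------- aggregates

def test_summarize_group_percentages():
    rule = ArrestRule.from_mean_sd(0.21, 0.05)
    tracks = [straight_track(120, (1.0, 0.0), cell_id=0),
              straight_track(120, (-1.0, 0.0), cell_id=1),
              straight_track(120, (0.0, 1.0), cell_id=2),
              straight_track(120, (0.0, -1.0), cell_id=3)]
    ts = TrackSet("g", tracks, dt=1.0)
    per_cell, agg = summarize_group(ts, [Window.short_term(), Window.long_term()],
                                    rule)
    assert len(per_cell) == 8  # 4 cells x 2 windows
    for _, row in agg.iterrows():
        assert row.percent_cells_with == 25.0
        assert row.percent_cells_against == 25.0
    single = summarize_group(TrackSet("g", [tracks[0]], dt=1.0),
                             [Window.long_term()], rule)[1]
    assert single.iloc[0]["displacement_um_mean"] == pytest.approx(120.0)
    assert single.iloc[0]["displacement_um_sem"] == 0.0


# ------------------------------------------------------ property checks

@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(-50, 50), st.floats(-50, 50))
def test_metrics_invariant_under_translation(seed, ox, oy):
    params = SimParams(n_cells=2, n_frames=20, base_speed=0.5, speed_sd=0.1,
                       p_pause=0.1, p_resume=0.3, pause_speed=0.05)
    ts = simulate_trackset(params, np.random.default_rng(seed))
    shifted = TrackSet("g", [Track(tr.cell_id, tr.t_min, tr.xy + [ox, oy])
                             for tr in ts.tracks], dt=ts.dt)
    for tr, trs in zip(ts.tracks, shifted.tracks):
        assert displacement(trs) == pytest.approx(displacement(tr), rel=1e-9, abs=1e-9)
        assert path_length(trs) == pytest.approx(path_length(tr), rel=1e-9, abs=1e-9)
    np.testing.assert_allclose(rms_displacement_curve(ts).rms,
                               naive_rms_curve(shifted), atol=1e-9)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 10.0))
def test_metrics_scale_equivariance(seed, c):
    params = SimParams(n_cells=2, n_frames=15, base_speed=0.5, speed_sd=0.1)
    ts = simulate_trackset(params, np.random.default_rng(seed))
    scaled = TrackSet("g", [Track(tr.cell_id, tr.t_min, tr.xy * c)
                            for tr in ts.tracks], dt=ts.dt)
    rule = ArrestRule.from_mean_sd(0.3, 0.05)
    scaled_rule = ArrestRule.from_mean_sd(0.3 * c, 0.05 * c)
    dir_rule = DirectionRule()
    for tr, trc in zip(ts.tracks, scaled.tracks):
        assert displacement(trc) == pytest.approx(c * displacement(tr), rel=1e-9)
        assert path_length(trc) == pytest.approx(c * path_length(tr), rel=1e-9)
        assert confinement_ratio(trc) == pytest.approx(confinement_ratio(tr),
                                                       rel=1e-9, abs=1e-12)
        assert (arrest_coefficient(trc, scaled_rule)
                == pytest.approx(arrest_coefficient(tr, rule), abs=1e-12))
        assert net_direction_class(trc, dir_rule) == net_direction_class(tr, dir_rule)
    np.testing.assert_allclose(rms_displacement_curve(scaled).rms,
                               c * rms_displacement_curve(ts).rms, rtol=1e-12)


def test_direction_equivariant_under_joint_rotation():
    rng = np.random.default_rng(21)
    params = SimParams(n_cells=5, n_frames=20, base_speed=0.5, speed_sd=0.1,
                       bias_kappa=0.4)
    ts = simulate_trackset(params, rng)
    phi = 0.7
    R = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
    rotated = TrackSet("g", [Track(tr.cell_id, tr.t_min, tr.xy @ R.T)
                             for tr in ts.tracks], dt=ts.dt)
    rule0 = DirectionRule(flow_angle=0.0)
    rule_phi = DirectionRule(flow_angle=phi)
    for tr, trr in zip(ts.tracks, rotated.tracks):
        assert (net_direction_class(trr, rule_phi)
                == net_direction_class(tr, rule0))
        assert time_direction_fractions(trr, rule_phi) == pytest.approx(
            time_direction_fractions(tr, rule0))


def test_full_window_equals_whole_track(small_trackset):
    w = Window(0.0, float(small_trackset.tracks[0].t_min[-1]))
    for tr in small_trackset.tracks:
        assert displacement(tr, w) == displacement(tr)
        assert path_length(tr, w) == path_length(tr)
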