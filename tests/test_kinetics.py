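"""Sister pairing, inter/intra-kinetochore distances, oscillation autocorrelation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spindlemetrics import (
    Channel,
    SimConfig,
    SisterPair,
    Track,
    axis_position_series,
    half_period,
    inter_kt_series,
    intra_kt_delta,
    oscillation_autocorrelation,
    pair_sisters,
    pair_tracks,
    simulate_cell,
)
from spindlemetrics.linking import link_tracks


def _track(xs, frames=None):
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    if xs.shape[1] != 3:
        xs = np.stack([xs.ravel(), np.zeros(xs.size), np.zeros(xs.size)], axis=1)
    frames = np.arange(len(xs)) if frames is None else np.asarray(frames)
    return Track(Channel.KT_INNER, frames, xs, np.ones(len(xs)))


def test_isolated_pair_is_found():
    pts = np.array([[0, 0, 0], [1.0, 0, 0], [8, 0, 0], [14, 0, 0]], dtype=float)
    pairs, unpaired = pair_sisters(pts, max_pair_um=2.0)
    assert pairs == [(0, 1)]
    assert set(unpaired) == {2, 3}


def test_three_collinear_points_greedy_trace():
    # 0 and 1 pair first (tie with 1-2 broken by lowest index); 2 left over
    pts = np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
    pairs, unpaired = pair_sisters(pts, max_pair_um=2.0)
    assert pairs == [(0, 1)]
    assert unpaired == [2]


def test_noiseless_simulator_pairs_match_ground_truth():
    cfg = SimConfig(noise_sigma_um=0.0, osc_amplitude_um=0.0, duration_s=15.0, seed=9)
    cell, truth = simulate_cell(cfg, 0)
    tracks = link_tracks(cell.detections, 1.0, channel=Channel.KT_INNER).tracks
    ps = pair_tracks(tracks, 2.0)
    assert len(ps.pairs) == cfg.n_pairs and ps.n_unpaired == 0
    true_pairs = {
        frozenset([tuple(np.round(truth.sister_ref[0, i], 9)),
                   tuple(np.round(truth.sister_other[0, i], 9))])
        for i in range(cfg.n_pairs)
    }
    got = {
        frozenset([tuple(np.round(p.track_a.positions[0], 9)),
                   tuple(np.round(p.track_b.positions[0], 9))])
        for p in ps.pairs
    }
    assert got == true_pairs


def test_pairing_robust_to_noise_at_study_conditions():
    # noise up to 0.1 um with 1 um rest length and >=1.5 um plate spacing
    cfg = SimConfig(noise_sigma_um=0.1, duration_s=15.0, seed=10)
    cell, truth = simulate_cell(cfg, 0)
    tracks = link_tracks(cell.detections, 1.0, channel=Channel.KT_INNER).tracks
    ps = pair_tracks(tracks, 2.0)
    assert len(ps.pairs) == cfg.n_pairs and ps.n_unpaired == 0
    for p in ps.pairs:
        d = np.linalg.norm(p.track_a.positions[0] - p.track_b.positions[0])
        assert 0.5 < d < 1.5  # true sisters, not cross-plate neighbors


def test_inter_kt_series_constant_and_gap():
    a = _track(np.zeros(5))
    b = _track(np.full(5, 1.0))
    np.testing.assert_allclose(inter_kt_series(SisterPair(a, b)), 1.0)
    b_gap = _track([1.0, 1.0, 1.0, 1.0], frames=[0, 1, 3, 4])
    s = inter_kt_series(SisterPair(a, b_gap))
    assert np.isnan(s[2]) and np.isfinite(s[[0, 1, 3, 4]]).all()


def test_antiphase_sisters_oscillate_at_drive_frequency():
    t = np.arange(40) * 7.5
    x_a = 0.2 * np.sin(2 * np.pi * t / 60.0)
    pair = SisterPair(_track(0.5 + x_a), _track(-0.5 - x_a))
    d = inter_kt_series(pair)
    # closed form: distance = 1 + 0.4 sin(2 pi t / 60)
    np.testing.assert_allclose(d, 1.0 + 0.4 * np.sin(2 * np.pi * t / 60.0), atol=1e-12)


def test_intra_kt_delta_examples():
    assert intra_kt_delta(1.00, 1.22) == pytest.approx(0.11)
    assert intra_kt_delta(0.8, 0.8) == 0.0
    assert intra_kt_delta(1.1, 1.0) == pytest.approx(-0.05)  # negative allowed


@given(
    d_in=st.floats(min_value=0, max_value=10),
    d_out=st.floats(min_value=0, max_value=10),
    a=st.floats(min_value=0.01, max_value=100),
)
def test_intra_kt_delta_is_linear(d_in, d_out, a):
    assert intra_kt_delta(a * d_in, a * d_out) == pytest.approx(
        a * intra_kt_delta(d_in, d_out), rel=1e-9, abs=1e-12
    )


def test_axis_position_sign_convention(noiseless_cell):
    from spindlemetrics import analyze_cell

    cell, truth = noiseless_cell
    res = analyze_cell(cell)
    geo0 = res.geometry_by_frame[0]
    u = geo0.axis_dir
    mid = (geo0.pole_ref_centroid + geo0.pole_other_centroid) / 2
    # a pair sitting toward the reference pole has positive axis position
    pair = SisterPair(
        _track((mid + 2.0 * u)[None, :], frames=[0]),
        _track((mid + 2.0 * u)[None, :], frames=[0]),
    )
    s = axis_position_series(pair, res.geometry_by_frame, np.array([0]))
    assert s[0] == pytest.approx(2.0, abs=1e-9)


def test_autocorrelation_of_sinusoid_matches_cosine():
    dt = 7.5
    t = np.arange(160) * dt
    x = np.sin(2 * np.pi * t / 80.0)
    prof = oscillation_autocorrelation(x, dt, max_lag_s=150.0)
    assert prof.ac[0] == 1.0
    expected = np.cos(2 * np.pi * prof.lags_s / 80.0) * (1 - prof.lags_s / (dt * len(t)))
    np.testing.assert_allclose(prof.ac, expected, atol=0.03)


def test_autocorrelation_of_white_noise_is_flat(rng):
    x = rng.normal(size=400)
    prof = oscillation_autocorrelation(x, 7.5, max_lag_s=150.0)
    assert np.all(np.abs(prof.ac[1:]) < 3 / np.sqrt(len(x)))


def test_autocorrelation_rejects_constant_and_gappy_series():
    with pytest.raises(ValueError, match="variance"):
        oscillation_autocorrelation(np.ones(20), 7.5)
    x = np.sin(np.arange(20.0))
    x[:6] = np.nan  # 30% gaps
    with pytest.raises(ValueError, match="gaps"):
        oscillation_autocorrelation(x, 7.5)
    with pytest.raises(ValueError, match="valid samples"):
        oscillation_autocorrelation(np.sin(np.arange(5.0)), 7.5)


@pytest.mark.parametrize(
    "period,expected_lag",
    [(40.0, 22.5), (60.0, 30.0), (80.0, 37.5), (120.0, 60.0)],
)
def test_half_period_on_lag_grid(period, expected_lag):
    # the first AC minimum sits at the grid lag nearest T/2 (within one dt)
    dt = 7.5
    t = np.arange(160) * dt
    prof = oscillation_autocorrelation(np.sin(2 * np.pi * t / period), dt, 150.0)
    lag, depth = half_period(prof)
    assert lag == expected_lag
    assert abs(lag - period / 2) <= dt
    assert depth < -0.8


def test_half_period_none_for_white_noise(rng):
    # long series so the AC noise floor (~1/sqrt(N)) sits well above -0.1
    prof = oscillation_autocorrelation(rng.normal(size=1000), 7.5, 150.0)
    lag, depth = half_period(prof)
    assert lag is None and depth is None
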