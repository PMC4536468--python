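"""Spindle geometry: pole clustering, plane fitting, half-spindle ratio R."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spindlemetrics import (
    ConfigLabel,
    GeometryError,
    Pole,
    assign_reference_pole,
    cluster_poles,
    fit_plate_plane,
    monopole_kt_distances,
    plate_metrics,
    pole_intensity_asymmetry,
    spindle_center_offset,
)


def _pole(centroid):
    centroid = np.asarray(centroid, dtype=float)
    return Pole(centroid=centroid, member_positions=centroid[None, :],
                member_intensities=np.array([100.0]))


def _exhaustive_partition(positions):
    """Independent oracle: best 2-group split by brute-force enumeration."""
    n = len(positions)
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=2)
    best = None
    for r in range(1, n):
        for a in itertools.combinations(range(n), r):
            b = tuple(i for i in range(n) if i not in a)
            if 0 not in a:
                continue
            cost = sum(d[i, j] for i, j in itertools.combinations(a, 2)) + sum(
                d[i, j] for i, j in itertools.combinations(b, 2)
            )
            if best is None or cost < best[0]:
                best = (cost, frozenset(map(frozenset, (a, b))))
    return best[1]


def test_two_tight_pairs_split_two_plus_two(rng):
    a = np.array([5.0, 0, 0]) + rng.normal(0, 0.1, (2, 3))
    b = np.array([-5.0, 0, 0]) + rng.normal(0, 0.1, (2, 3))
    pos = np.vstack([a, b])
    p1, p2 = cluster_poles(pos, np.array([400.0, 200, 300, 200]))
    assert {p1.n_centrioles, p2.n_centrioles} == {2}
    got = {tuple(np.round(p.centroid, 6)) for p in (p1, p2)}
    want = {tuple(np.round(a.mean(0), 6)), tuple(np.round(b.mean(0), 6))}
    assert got == want


def test_three_point_split_matches_exhaustive_oracle(rng):
    for _ in range(20):
        pair = np.array([5.0, 0, 0]) + rng.normal(0, 0.3, (2, 3))
        lone = np.array([-5.0, 0, 0]) + rng.normal(0, 0.3, (1, 3))
        pos = np.vstack([pair, lone])
        perm = rng.permutation(3)
        p1, p2 = cluster_poles(pos[perm], np.array([400.0, 300, 200])[perm])
        oracle = _exhaustive_partition(pos[perm])
        got = frozenset(
            frozenset(int(np.argmin(np.linalg.norm(pos[perm] - m, axis=1)))
                      for m in p.member_positions)
            for p in (p1, p2)
        )
        assert got == oracle
        assert {p1.n_centrioles, p2.n_centrioles} == {1, 2}


def test_two_points_split_one_one():
    pos = np.array([[5.0, 0, 0], [-5.0, 0, 0]])
    p1, p2 = cluster_poles(pos, np.array([400.0, 300.0]))
    assert p1.n_centrioles == p2.n_centrioles == 1


def test_single_detection_is_error():
    with pytest.raises(GeometryError):
        cluster_poles(np.array([[0.0, 0, 0]]), np.array([1.0]))


def test_reference_pole_conventions():
    two = Pole(np.zeros(3), np.array([[0.1, 0, 0], [-0.1, 0, 0]]), np.array([300.0, 200]))
    one = Pole(np.array([10.0, 0, 0]), np.array([[10.0, 0, 0]]), np.array([400.0]))
    # 2:1 cells: the 2-centriole pole wins even though the other is brighter
    assert assign_reference_pole((two, one), ConfigLabel.C21) == 0
    assert assign_reference_pole((one, two), ConfigLabel.C21) == 1
    # otherwise the brightest single centriole (grandmother) wins
    assert assign_reference_pole((two, one), ConfigLabel.C22) == 1
    assert assign_reference_pole((two, one), ConfigLabel.C11) == 1
    tie = Pole(np.zeros(3), np.zeros((1, 3)), np.array([400.0]))
    with pytest.raises(GeometryError, match="tie"):
        assign_reference_pole((tie, one), ConfigLabel.C22)


def test_plane_fit_exact_on_coplanar_points():
    pts = np.array([[0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    n, d = fit_plate_plane(pts)
    assert abs(abs(n[0]) - 1.0) < 1e-12
    assert abs(d) < 1e-12


def test_plane_fit_recovers_constructed_plane(rng):
    # 100 random points on x + y = 1
    a = rng.uniform(-3, 3, 100)
    z = rng.uniform(-3, 3, 100)
    pts = np.stack([a, 1.0 - a, z], axis=1)
    n, d = fit_plate_plane(pts)
    expected = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    if n @ expected < 0:
        n, d = -n, -d
    np.testing.assert_allclose(n, expected, atol=1e-9)
    assert d == pytest.approx(1 / np.sqrt(2), abs=1e-9)
    residual = np.abs(pts @ n - d)
    assert residual.max() < 1e-9


def test_plane_fit_beats_random_candidate_planes(rng):
    pts = rng.normal(size=(40, 3)) * np.array([3.0, 3.0, 0.3])
    n, d = fit_plate_plane(pts)
    fitted = np.sum((pts @ n - d) ** 2)
    # random-search oracle: 10^4 random unit normals through the centroid
    cand = rng.normal(size=(10_000, 3))
    cand /= np.linalg.norm(cand, axis=1, keepdims=True)
    proj = (pts - pts.mean(axis=0)) @ cand.T
    residuals = np.sum(proj**2, axis=0)
    assert fitted <= residuals.min() + 1e-9


def test_plane_fit_rejects_collinear_points():
    pts = np.stack([np.linspace(0, 1, 5), np.zeros(5), np.zeros(5)], axis=1)
    with pytest.raises(GeometryError, match="collinear"):
        fit_plate_plane(pts)


def test_plate_metrics_axis_aligned_arithmetic():
    poles = (_pole([5.0, 0, 0]), _pole([-5.0, 0, 0]))
    g = plate_metrics((np.array([1.0, 0, 0]), 0.5), poles, reference_pole=0)
    assert g.L1 == pytest.approx(4.5)
    assert g.L2 == pytest.approx(5.5)
    assert g.R == pytest.approx(4.5 / 5.5)
    g0 = plate_metrics((np.array([1.0, 0, 0]), 0.0), poles, reference_pole=0)
    assert g0.R == pytest.approx(1.0)


def test_plate_metrics_oblique_plane():
    poles = (_pole([5.0, 0, 0]), _pole([-5.0, 0, 0]))
    n = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    g = plate_metrics((n, 1.0 / np.sqrt(2)), poles, reference_pole=0)
    np.testing.assert_allclose(g.intersection, [1.0, 0, 0], atol=1e-12)
    assert g.L1 == pytest.approx(4.0)
    assert g.L2 == pytest.approx(6.0)
    assert g.R == pytest.approx(2.0 / 3.0)


def test_plate_metrics_parallel_axis_is_error():
    poles = (_pole([5.0, 0, 0]), _pole([-5.0, 0, 0]))
    with pytest.raises(GeometryError, match="parallel"):
        plate_metrics((np.array([0.0, 1.0, 0]), 0.0), poles, reference_pole=0)


def test_plate_metrics_outside_segment_flagged_not_fatal():
    poles = (_pole([5.0, 0, 0]), _pole([-5.0, 0, 0]))
    with pytest.warns(UserWarning):
        g = plate_metrics((np.array([1.0, 0, 0]), 7.0), poles, reference_pole=0)
    assert not g.between_poles
    assert g.R == pytest.approx(2.0 / 12.0)


def test_r_inverts_under_reference_swap(rng):
    for _ in range(20):
        p = [_pole(rng.normal(0, 5, 3)) for _ in range(2)]
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        d = rng.normal()
        u = p[0].centroid - p[1].centroid
        if abs(n @ u / np.linalg.norm(u)) < 1e-3:
            continue
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = plate_metrics((n, d), (p[0], p[1]), 0).R
            r2 = plate_metrics((n, d), (p[0], p[1]), 1).R
        assert r1 * r2 == pytest.approx(1.0, rel=1e-12)


def test_geometry_invariant_under_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    kts = rng.normal(size=(30, 3)) * np.array([0.3, 3.0, 3.0])
    poles_pos = np.array([[5.0, 0.2, -0.1], [-5.0, -0.3, 0.2]])
    cortex = np.array([[7.5, 0.5, 0], [-8.5, -0.5, 0]])

    def compute(kpts, ppos, cpts):
        poles = (_pole(ppos[0]), _pole(ppos[1]))
        plane = fit_plate_plane(kpts)
        g = plate_metrics(plane, poles, 0)
        off = spindle_center_offset(poles, cpts)
        return g.L1, g.L2, g.R, off

    base = compute(kts, poles_pos, cortex)
    rot = Rotation.random(random_state=7).as_matrix()
    shift = np.array([10.0, -3.0, 2.0])
    moved = compute(kts @ rot.T + shift, poles_pos @ rot.T + shift, cortex @ rot.T + shift)
    np.testing.assert_allclose(moved, base, atol=1e-9)


def test_spindle_center_offset_examples():
    poles = (_pole([5.0, 0, 0]), _pole([-5.0, 0, 0]))
    off = spindle_center_offset(poles, np.array([[-7.0, 0, 0], [9.0, 0, 0]]))
    assert off == pytest.approx(1.0)
    sym = spindle_center_offset(poles, np.array([[8.0, 0, 0], [-8.0, 0, 0]]))
    assert sym == pytest.approx(0.0)
    with pytest.raises(GeometryError, match="one side"):
        spindle_center_offset(poles, np.array([[8.0, 0, 0], [9.0, 0, 0]]))


def test_spindle_center_offset_matches_brute_force(rng):
    # tilted axis, off-axis cortex points: compare with explicit projections
    for _ in range(10):
        p1, p2 = rng.normal(0, 4, (2, 3))
        poles = (_pole(p1), _pole(p2))
        mid = (p1 + p2) / 2
        u = (p1 - p2) / np.linalg.norm(p1 - p2)
        cortex = np.vstack(
            [mid + rng.uniform(6, 9) * u + rng.normal(0, 0.5, 3),
             mid - rng.uniform(6, 9) * u + rng.normal(0, 0.5, 3),
             mid + rng.uniform(6, 9) * u + rng.normal(0, 2.0, 3),
             mid - rng.uniform(6, 9) * u + rng.normal(0, 2.0, 3)]
        )
        got = spindle_center_offset(poles, cortex)
        # independent re-computation
        s = (cortex - mid) @ u
        perp = np.linalg.norm((cortex - mid) - np.outer(s, u), axis=1)
        pos_i = min((i for i in range(4) if s[i] > 0), key=lambda i: perp[i])
        neg_i = min((i for i in range(4) if s[i] < 0), key=lambda i: perp[i])
        cc = (mid + s[pos_i] * u + mid + s[neg_i] * u) / 2
        assert got == pytest.approx(np.linalg.norm(mid - cc), abs=1e-9)


def test_monopole_distances():
    kts = np.array([[2.0, 0, 0], [0, 2.0, 0], [0, 0, -2.0]])
    d = monopole_kt_distances(kts, np.zeros((1, 3)))
    np.testing.assert_allclose(d, 2.0)
    # nearest of two centrioles wins
    d2 = monopole_kt_distances(np.array([[3.0, 0, 0]]), np.array([[0.0, 0, 0], [4.0, 0, 0]]))
    assert d2[0] == pytest.approx(1.0)
    # a shrunk kinetochore shell shifts the mean by the shell difference
    sphere = np.random.default_rng(0).normal(size=(200, 3))
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    m2 = monopole_kt_distances(2.0 * sphere, np.zeros((1, 3))).mean()
    m15 = monopole_kt_distances(1.5 * sphere, np.zeros((1, 3))).mean()
    assert m2 - m15 == pytest.approx(0.5, abs=1e-9)


def test_pole_intensity_asymmetry_values():
    assert pole_intensity_asymmetry(100, 100) == 0.0
    assert pole_intensity_asymmetry(150, 50) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        pole_intensity_asymmetry(0.0, 0.0)


@given(
    i1=st.floats(min_value=0.0, max_value=1e6),
    i2=st.floats(min_value=0.0, max_value=1e6),
)
def test_pole_intensity_asymmetry_antisymmetric_and_bounded(i1, i2):
    if i1 + i2 == 0:
        return
    v = pole_intensity_asymmetry(i1, i2)
    assert -1.0 <= v <= 1.0
    assert v == pytest.approx(-pole_intensity_asymmetry(i2, i1), abs=1e-12)
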