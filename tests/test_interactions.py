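"""Geometric H-bonds, COM-distance metrics and contact-event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unbend.interactions import (DistanceMetricSpec, HBondCriteria,
                                 com_distance_series, detect_contact_event,
                                 find_hbonds, hbond_count_series)
from unbend.model_io import Trajectory

from conftest import make_atoms


def _dha_model(da_distance, angle_deg):
    """Donor at origin, hydrogen 1 Å out, acceptor at the given D-A
    distance with the given D-H-A angle (vertex at H)."""
    d = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    # place A such that angle D-H-A = angle_deg and |D-A| = da_distance
    theta = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # solve |h + s*direction - d| = da_distance for s > 0
    b = 2 * h @ direction
    c = h @ h - da_distance ** 2
    s = (-b + np.sqrt(b * b - 4 * c)) / 2
    a = h + s * direction
    return make_atoms([d, h, a], roles=["donor", "hydrogen", "acceptor"],
                      donor_links=[-1, 1, -1])


@pytest.mark.parametrize("dist,angle,expected", [
    (3.4, 150.0, 1),     # inside both thresholds
    (3.6, 150.0, 0),     # too far
    (3.4, 110.0, 0),     # too bent
])
def test_hbond_geometric_criterion(dist, angle, expected):
    m = _dha_model(dist, angle)
    bonds = find_hbonds(m, [1, 2], [3])
    assert len(bonds) == expected
    if expected:
        assert bonds[0] == (1, 2, 3)


def test_hbond_distance_boundary_is_strict():
    """A collinear D-H···A pair at exactly 3.5 Å is not counted."""
    m = make_atoms([[0.0, 0, 0], [1.0, 0, 0], [3.5, 0, 0]],
                   roles=["donor", "hydrogen", "acceptor"],
                   donor_links=[-1, 1, -1])
    assert find_hbonds(m, [1, 2], [3]) == []
    m2 = make_atoms([[0.0, 0, 0], [1.0, 0, 0], [3.4999, 0, 0]],
                    roles=["donor", "hydrogen", "acceptor"],
                    donor_links=[-1, 1, -1])
    assert find_hbonds(m2, [1, 2], [3]) == [(1, 2, 3)]


def test_hbond_symmetric_in_group_labels(model, topology):
    hyb = model.serial[topology.domains["hybrid"]]
    td = model.serial[topology.domains["betaTD"]]
    ab = find_hbonds(model, hyb, td)
    ba = find_hbonds(model, td, hyb)
    assert ab == ba
    assert len(ab) >= 4


def _random_polar_model(rng, n=50):
    roles, links = [], []
    pos = rng.uniform(0, 12, size=(n, 3))
    for i in range(n):
        r = rng.choice(["donor", "acceptor", "none"], p=[0.35, 0.45, 0.2])
        roles.append(r)
        links.append(-1)
    # attach one hydrogen next to each donor
    extra_pos, extra_roles, extra_links = [], [], []
    for i, r in enumerate(roles):
        if r == "donor":
            extra_pos.append(pos[i] + rng.normal(scale=0.6, size=3))
            extra_roles.append("hydrogen")
            extra_links.append(i + 1)
    allpos = np.vstack([pos, np.array(extra_pos)])
    return make_atoms(allpos, roles=roles + extra_roles,
                      donor_links=links + extra_links)


def _brute_force_hbonds(m, group_a, group_b, crit=HBondCriteria()):
    """Exhaustive loop over all (donor, hydrogen, acceptor) triples."""
    rows = {int(s): i for i, s in enumerate(m.serial)}
    out = {}
    for ga, gb in ((group_a, group_b), (group_b, group_a)):
        ga, gb = set(map(int, ga)), set(map(int, gb))
        for hs in m.serial:
            h = rows[int(hs)]
            if m.role[h] != "hydrogen" or int(hs) not in ga:
                continue
            d = rows.get(int(m.donor_link[h]))
            if d is None or int(m.serial[d]) not in ga:
                continue
            for as_ in gb:
                a = rows[as_]
                if m.role[a] not in ("acceptor", "donor") or a == d:
                    continue
                if np.linalg.norm(m.xyz[a] - m.xyz[d]) >= crit.max_da_distance:
                    continue
                v1 = m.xyz[d] - m.xyz[h]
                v2 = m.xyz[a] - m.xyz[h]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang <= crit.min_dha_angle:
                    continue
                key = (int(m.serial[d]), as_)
                prev = out.get(key)
                if prev is None or ang > prev[1]:
                    out[key] = (int(hs), ang)
    return sorted((d, h, a) for (d, a), (h, _) in out.items())


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 10 ** 6))
def test_hbonds_match_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    m = _random_polar_model(rng)
    half = m.n_atoms // 2
    group_a = [int(s) for s in m.serial[:half]]
    group_b = [int(s) for s in m.serial[half:]]
    assert find_hbonds(m, group_a, group_b) == _brute_force_hbonds(
        m, group_a, group_b)


def test_hbond_count_invariant_under_rigid_motion(model, topology):
    from scipy.spatial.transform import Rotation
    hyb = model.serial[topology.domains["hybrid"]]
    td = model.serial[topology.domains["betaTD"]]
    n0 = len(find_hbonds(model, hyb, td))
    rot = Rotation.random(random_state=7).as_matrix()
    moved = model.xyz @ rot.T + np.array([10.0, -3.0, 2.0])
    assert len(find_hbonds(model, hyb, td, coords=moved)) == n0


def test_hbond_count_series_constant_on_static_frames(model, topology):
    hyb = model.serial[topology.domains["hybrid"]]
    td = model.serial[topology.domains["betaTD"]]
    traj = Trajectory(times=np.arange(3.0),
                      coords=np.repeat(model.xyz[None], 3, axis=0))
    counts = hbond_count_series(traj, model, hyb, td)
    assert counts["count"].nunique() == 1
    assert counts["count"].iloc[0] >= 4


def test_hbond_empty_group_gives_zero(model, topology):
    betaA = model.serial[topology.domains["betaA"]]   # no polar beads
    td = model.serial[topology.domains["betaTD"]]
    assert find_hbonds(model, betaA, td) == []


def test_com_distance_series_cases():
    m = make_atoms([[0.0, 0, 0], [0, 0, 0], [3.0, 4.0, 0]])
    traj = Trajectory(times=np.array([0.0, 1.0]),
                      coords=np.repeat(m.xyz[None], 2, axis=0))
    spec = DistanceMetricSpec("d", (1,), (2,))
    np.testing.assert_allclose(
        com_distance_series(traj, m, spec)[:, 1], 0.0, atol=1e-12)
    spec2 = DistanceMetricSpec("d2", (1, 2), (3,))
    np.testing.assert_allclose(
        com_distance_series(traj, m, spec2)[:, 1], 5.0, atol=1e-12)


def test_com_distance_matches_brute_force():
    rng = np.random.default_rng(9)
    m = make_atoms(rng.normal(size=(6, 3)))
    coords = rng.normal(size=(4, 6, 3)) * 5
    traj = Trajectory(times=np.arange(4.0), coords=coords)
    spec = DistanceMetricSpec("m", (1, 3), (4, 5, 6))
    got = com_distance_series(traj, m, spec)[:, 1]
    want = [np.linalg.norm(c[[0, 2]].mean(0) - c[[3, 4, 5]].mean(0))
            for c in coords]
    np.testing.assert_allclose(got, want, atol=1e-12)


# ---------------------------------------------------------------------------
# contact events
# ---------------------------------------------------------------------------


def _step_series(t_step=18.0, before=14.0, after=3.5, t_end=40.0, dt=0.5):
    t = np.arange(0, t_end + dt, dt)
    v = np.where(t < t_step, before, after)
    return np.column_stack([t, v])


def test_contact_event_step_trace():
    """A 14 → 3.5 Å drop at t = 18 ns under a <4 Å rule detects at 18 ns."""
    spec = DistanceMetricSpec("ion", (1,), (2,), threshold=4.0,
                              direction="below", hold_time=1.0)
    assert detect_contact_event(_step_series(), spec) == 18.0


def test_contact_event_none_when_never_crossing():
    spec = DistanceMetricSpec("ion", (1,), (2,), threshold=4.0,
                              direction="below", hold_time=1.0)
    series = _step_series(before=14.0, after=14.0)
    assert detect_contact_event(series, spec) is None


def test_contact_event_requires_hold():
    spec = DistanceMetricSpec("ion", (1,), (2,), threshold=4.0,
                              direction="below", hold_time=5.0)
    t = np.arange(0, 41.0, 0.5)
    v = np.full_like(t, 14.0)
    v[(t >= 10) & (t < 12)] = 3.0   # 2 ns dip: shorter than the hold
    v[t >= 30] = 3.0                # sustained to the end
    series = np.column_stack([t, v])
    assert detect_contact_event(series, spec) == 30.0


def test_contact_event_invariant_to_appended_frames():
    spec = DistanceMetricSpec("ion", (1,), (2,), threshold=4.0,
                              direction="below", hold_time=1.0)
    base = _step_series()
    longer = np.vstack([base, np.column_stack([base[-1, 0] + np.arange(1, 11),
                                               np.full(10, 14.0)])])
    assert (detect_contact_event(base, spec)
            == detect_contact_event(longer, spec))


def _brute_force_event(series, spec):
    t, v = series[:, 0], series[:, 1]
    for i in range(len(t)):
        ok = v[i] < spec.threshold if spec.direction == "below" else \
            v[i] > spec.threshold
        if not ok:
            continue
        j = i
        while j < len(t) and (v[j] < spec.threshold
                              if spec.direction == "below"
                              else v[j] > spec.threshold):
            j += 1
        if t[j - 1] - t[i] >= spec.hold_time:
            return float(t[i])
    return None


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10 ** 6))
def test_contact_event_matches_scan_oracle(seed):
    rng = np.random.default_rng(seed)
    t = np.arange(0, 50.0, 0.25)
    v = 10.0 + np.cumsum(rng.normal(scale=0.8, size=len(t)))
    series = np.column_stack([t, np.abs(v)])
    spec = DistanceMetricSpec("x", (1,), (2,), threshold=6.0,
                              direction="below", hold_time=2.0)
    assert detect_contact_event(series, spec) == _brute_force_event(series, spec)


def test_contact_event_hold_longer_than_series():
    spec = DistanceMetricSpec("x", (1,), (2,), threshold=4.0, hold_time=100.0)
    with pytest.raises(ValueError, match="hold time"):
        detect_contact_event(_step_series(), spec)
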