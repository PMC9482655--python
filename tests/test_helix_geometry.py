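"""Axis fitting, crossing angles, bundle detection, distortion."""
import numpy as np
import pytest

from conftest import random_rigid_motion
from istfold.helixgeom import (classify_orientation, crossing_angle,
                               distortion_score, find_bundles, fit_axis,
                               helix_axes, triangular_face)
from istfold.sse import assign_sse
from istfold.structure import Structure
from istfold.synth import (HelixSpec, MimicSpec, crossed_helix_pair,
                           make_ideal_helix, make_ist_mimic, perturb)


def _ca(st: Structure) -> np.ndarray:
    return st.coords(atom_name="CA")


def test_fit_axis_recovers_direction():
    d = np.array([0.0, 0.0, 1.0])
    ax = fit_axis(_ca(make_ideal_helix(HelixSpec(12, direction=d))))
    assert np.degrees(np.arccos(abs(ax.direction @ d))) < 1.0
    assert ax.direction @ d > 0  # oriented N -> C


def test_fit_axis_needs_four_ca():
    with pytest.raises(ValueError):
        fit_axis(np.zeros((3, 3)))


def test_straightness_of_ideal_helix():
    ax = fit_axis(_ca(make_ideal_helix(HelixSpec(15))))
    assert ax.straightness > 0.999


def test_bent_helix_detected():
    """30-degree kink at the midpoint lowers straightness and the local
    axis direction turns by about the kink angle."""
    st = make_ideal_helix(HelixSpec(20))
    ca = _ca(st)
    from istfold._geom import rotation_about_axis
    R = rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.deg2rad(30))
    pivot = ca[10]
    bent = ca.copy()
    bent[10:] = (ca[10:] - pivot) @ R.T + pivot
    ax = fit_axis(bent)
    assert ax.straightness < 0.97
    lo = ax.local_points
    d1 = lo[4] - lo[0]
    d2 = lo[-1] - lo[-5]
    ang = np.degrees(np.arccos(
        np.dot(d1, d2) / np.linalg.norm(d1) / np.linalg.norm(d2)))
    assert 20 < ang < 40


@pytest.mark.parametrize("angle", [0.0, 20.0, 150.0, 180.0])
def test_crossing_angle_recovery(angle):
    if angle in (0.0, 180.0):
        a = fit_axis(_ca(make_ideal_helix(HelixSpec(12))))
        d = np.array([0, 0, 1.0]) if angle == 0 else np.array([0, 0, -1.0])
        b = fit_axis(_ca(make_ideal_helix(
            HelixSpec(12, origin=np.array([10.0, 0, 0]), direction=d))))
        got, dist = crossing_angle(a, b)
        assert abs(got - angle) < 1.0
        assert 9.0 < dist < 11.0
    else:
        st, truth = crossed_helix_pair(angle)
        ann = assign_sse(st, "A")
        axes = helix_axes(st, ann)
        assert len(axes) == 2
        got, _ = crossing_angle(axes[0], axes[1])
        assert abs(got - angle) < 2.0


def test_crossing_angle_symmetric():
    a = fit_axis(_ca(make_ideal_helix(HelixSpec(10))))
    b = fit_axis(_ca(make_ideal_helix(
        HelixSpec(10, origin=np.array([9.0, 2, 1]),
                  direction=np.array([0.2, 0.1, 1.0])))))
    assert crossing_angle(a, b) == crossing_angle(b, a)


def test_classify_orientation_threshold():
    assert classify_orientation(10.0) == "P"
    assert classify_orientation(170.0) == "AP"
    assert classify_orientation(90.0) == "AP"   # documented tie-break
    with pytest.raises(ValueError):
        classify_orientation(200.0)


def _bundle_axes(orientations):
    st, _ = make_ist_mimic(MimicSpec(
        orientations=orientations, perpendicular_helix=False,
        cxxc_sites=False, hinge_hairpin=False, sandwich_domain=False))
    ann = assign_sse(st, "A")
    return helix_axes(st, ann)


def test_find_bundles_alternating_and_control():
    cands = find_bundles(_bundle_axes(("up", "down", "up", "down")))
    assert cands and cands[0].alternating
    cands2 = find_bundles(_bundle_axes(("up", "up", "up", "up")))
    assert cands2 and not cands2[0].alternating


def test_find_bundles_needs_four():
    axes = _bundle_axes(("up", "down", "up", "down"))[:3]
    assert find_bundles(axes) == []


def test_triangular_face_detection_and_ablations():
    st, _ = make_ist_mimic(MimicSpec(cxxc_sites=False))
    ann = assign_sse(st, "A")
    axes = helix_axes(st, ann)
    bundle = find_bundles(axes)[0]
    in_bundle = {id(h.segment) for h in bundle.helices}
    short = [a for a in helix_axes(st, ann, "HG")
             if id(a.segment) not in in_bundle and 3 <= len(a.segment) <= 7]
    face = triangular_face(bundle, short)
    assert face is not None
    assert len(face["bundle_helices"]) == 2
    # collinear ablation: short helix parallel to the bundle
    st2, _ = make_ist_mimic(MimicSpec(cxxc_sites=False,
                                      perp_helix_collinear=True))
    ann2 = assign_sse(st2, "A")
    axes2 = helix_axes(st2, ann2)
    bundle2 = find_bundles(axes2)[0]
    in_b2 = {id(h.segment) for h in bundle2.helices}
    short2 = [a for a in helix_axes(st2, ann2, "HG")
              if id(a.segment) not in in_b2 and 3 <= len(a.segment) <= 7]
    assert triangular_face(bundle2, short2) is None
    # no extra helices at all
    assert triangular_face(bundle, []) is None


def test_distortion_regular_vs_displaced():
    axes = _bundle_axes(("up", "down", "up", "down"))
    regular = find_bundles(axes)[0]
    assert distortion_score(regular) < 0.02
    # tilt one helix so its top is displaced ~3 A
    st, _ = make_ist_mimic(MimicSpec(
        perpendicular_helix=False, cxxc_sites=False, hinge_hairpin=False,
        sandwich_domain=False))
    ann = assign_sse(st, "A")
    chain = st.chain("A")
    seg = ann.helix_segments("H")[0]
    z = np.array([chain[i]["CA"].pos[2] for i in seg.indices])
    span = z.max() - z.min()
    for i in seg.indices:
        for a in chain[i].atoms:
            frac = (a.pos[2] - z.min()) / span
            a.pos = a.pos + np.array([3.0 * frac, 0.0, 0.0])
    ann2 = assign_sse(st, "A")
    displaced = find_bundles(helix_axes(st, ann2))[0]
    assert distortion_score(displaced) > distortion_score(regular)


def test_distortion_rotation_invariant():
    axes = _bundle_axes(("up", "down", "up", "down"))
    st, _ = make_ist_mimic(MimicSpec(
        perpendicular_helix=False, cxxc_sites=False, hinge_hairpin=False,
        sandwich_domain=False))
    R, t = random_rigid_motion(4)
    st2 = st.transformed(R, t)
    b1 = find_bundles(helix_axes(st, assign_sse(st, "A")))[0]
    b2 = find_bundles(helix_axes(st2, assign_sse(st2, "A")))[0]
    assert np.isclose(distortion_score(b1), distortion_score(b2), atol=1e-6)
    assert np.allclose(b1.angles, b2.angles, atol=1e-6)
    assert np.allclose(b1.distances, b2.distances, atol=1e-6)


def test_orientation_recovery_grid():
    """P/AP classification is exact on the crossing-angle grid with 0.3 A
    noise, and angle recovery stays within 2 degrees without noise."""
    for angle in (0, 10, 20, 30, 40):
        for chirality in (1, -1):
            st, _ = crossed_helix_pair(chirality * angle)
            ann = assign_sse(st, "A")
            axes = helix_axes(st, ann)
            got, _ = crossing_angle(axes[0], axes[1])
            assert abs(got - abs(angle)) < 2.0
            for seed in range(20):
                stn = perturb(st, 0.3, seed)
                axn = helix_axes(stn, assign_sse(stn, "A"))
                gotn, _ = crossing_angle(axn[0], axn[1])
                assert classify_orientation(gotn) == "P"
            # antiparallel version of the same geometry
            st2, _ = crossed_helix_pair(180 - chirality * angle)
            ax2 = helix_axes(st2, assign_sse(st2, "A"))
            got2, _ = crossing_angle(ax2[0], ax2[1])
            assert classify_orientation(got2) == "AP"
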