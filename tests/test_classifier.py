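"""Hallmark classification, superposition, batch screening."""
import numpy as np
import pytest

from conftest import random_rigid_motion
from istfold.classify import batch_report, classify, superpose
from istfold.structure import write_structure
from istfold.synth import (HelixSpec, MimicSpec, izumo1_like_mimic,
                           make_ideal_helix, make_ist_mimic, perturb,
                           regular_parallel_bundle, synthetic_spaca6,
                           write_with_sidecar)


def test_reference_is_called_ist(reference_report):
    rep = reference_report
    assert rep.h1_alternating_4hb
    assert rep.h2_triangular_face
    assert rep.h3_dual_cxxc
    assert rep.has_ig_domain
    assert rep.ist_call
    assert rep.bundle.topology in (["P", "AP", "P", "AP"],
                                   ["AP", "P", "AP", "P"])
    assert len(rep.disulfides) == 6


def test_ist_call_is_conjunction_of_hallmarks(reference_report):
    rep = reference_report
    assert rep.ist_call == (rep.h1_alternating_4hb
                            and rep.h2_triangular_face
                            and rep.h3_dual_cxxc)


def test_mimic_without_ig_domain_is_still_ist():
    """Family members without the sandwich (the bundle-only relatives)
    still satisfy the three bundle hallmarks."""
    st, _ = make_ist_mimic(MimicSpec(sandwich_domain=False))
    rep = classify(st)
    assert rep.ist_call
    assert not rep.has_ig_domain


ABLATIONS = [
    ("h1_alternating_4hb", dict(orientations=("up", "up", "up", "up"))),
    ("h2_triangular_face", dict(perp_helix_collinear=True)),
    ("h3_dual_cxxc", dict(cxxc_sites=False)),
    ("h3_dual_cxxc", dict(broken_disulfide=True)),
]


@pytest.mark.parametrize("hallmark,kwargs", ABLATIONS)
@pytest.mark.parametrize("seed", [0, 1])
def test_single_ablations_flip_exactly_one_hallmark(hallmark, kwargs, seed):
    st, _ = make_ist_mimic(MimicSpec(noise_sigma=0.1, seed=seed, **kwargs))
    rep = classify(st)
    assert not rep.ist_call
    assert not getattr(rep, hallmark)
    for other in {"h1_alternating_4hb", "h2_triangular_face",
                  "h3_dual_cxxc"} - {hallmark}:
        assert getattr(rep, other)


def test_regular_parallel_bundle_rejected():
    st, _ = regular_parallel_bundle()
    rep = classify(st)
    assert not rep.h1_alternating_4hb
    assert not rep.ist_call


def test_too_short_chain_raises():
    st = make_ideal_helix(HelixSpec(20))
    with pytest.raises(ValueError, match="too short"):
        classify(st)


def test_classify_rigid_motion_invariant(reference):
    st, _ = reference
    rep = classify(st)
    R, t = random_rigid_motion(7)
    rep2 = classify(st.transformed(R, t))
    assert rep.ist_call == rep2.ist_call
    assert rep.bundle.topology == rep2.bundle.topology
    assert np.isclose(rep.bend_angle, rep2.bend_angle, atol=1e-6)
    assert [b.partners() for b in rep.disulfides] == \
        [b.partners() for b in rep2.disulfides]


def test_benchmark_sensitivity_specificity():
    """40-structure benchmark: 20 positives (varying bend, with and
    without the Ig domain), 20 negatives (single ablations and regular
    parallel bundles) at 0.1 A noise: perfect separation."""
    pos = neg = pos_ok = neg_ok = 0
    for seed in range(20):
        st, _ = make_ist_mimic(MimicSpec(
            bend_angle=10 + (seed % 4) * 15, noise_sigma=0.1, seed=seed,
            sandwich_domain=(seed % 2 == 0)))
        pos += 1
        pos_ok += int(classify(st).ist_call)
    for seed in range(16):
        _, kwargs = ABLATIONS[seed % 4]
        st, _ = make_ist_mimic(MimicSpec(noise_sigma=0.1, seed=seed,
                                         **kwargs))
        neg += 1
        neg_ok += int(not classify(st).ist_call)
    for seed in range(4):
        st, _ = regular_parallel_bundle()
        neg += 1
        neg_ok += int(not classify(perturb(st, 0.1, seed)).ist_call)
    assert pos_ok == pos == 20
    assert neg_ok == neg == 20


# --- superposition ---------------------------------------------------------

def test_superpose_identity_and_rigid_copy(reference):
    st, _ = reference
    rmsd, R, t = superpose(st, st)
    assert rmsd < 1e-12
    Rr, tr = random_rigid_motion(8)
    moved = st.transformed(Rr, tr)
    rmsd2, R2, t2 = superpose(st, moved)
    assert rmsd2 < 1e-6
    assert np.allclose(R2 @ Rr, np.eye(3), atol=1e-9)


def test_superpose_selection_and_mismatch(reference):
    st, _ = reference
    rmsd, _, _ = superpose(st, st, selection=(27, 100))
    assert rmsd < 1e-12
    with pytest.raises(ValueError, match="common"):
        superpose(st, st, selection=(1, 5))


def _quaternion_grid_rmsd(X, Y, n_coarse=4000, n_refine=3):
    """Brute-force rigid superposition: rotation sampled on a quaternion
    grid with local refinement; independent of the closed-form solution."""
    rng = np.random.default_rng(12345)
    X0 = X - X.mean(axis=0)
    Y0 = Y - Y.mean(axis=0)

    def rmsd_of(q):
        q = q / np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        d = X0 @ R.T - Y0
        return np.sqrt((d ** 2).sum() / len(X0))

    qs = rng.normal(size=(n_coarse, 4))
    best_q = min(qs, key=rmsd_of)
    best = rmsd_of(best_q)
    scale = 0.2
    for _ in range(n_refine * 400):
        cand = best_q + rng.normal(scale=scale, size=4)
        r = rmsd_of(cand)
        if r < best:
            best, best_q = r, cand
        else:
            scale = max(scale * 0.995, 1e-4)
    return best


def test_superpose_matches_quaternion_grid_oracle():
    rng = np.random.default_rng(4)
    X = rng.uniform(-10, 10, size=(50, 3))
    R, t = random_rigid_motion(9)
    Y = X @ R.T + t + rng.normal(scale=0.5, size=X.shape)
    from istfold.structure import Atom, Residue, Structure

    def as_structure(P, name):
        return Structure(name, [
            Residue("A", i + 1, "GLY", [Atom("CA", "C", p)])
            for i, p in enumerate(P)])

    rmsd, _, _ = superpose(as_structure(Y, "a"), as_structure(X, "b"))
    oracle = _quaternion_grid_rmsd(X, Y)
    assert rmsd <= oracle + 1e-9          # ours is the global optimum
    assert abs(rmsd - oracle) < 1e-3


def test_superpose_noisy_copy_scales_with_sigma(reference):
    """RMSD to an isotropically noised copy approaches sigma*sqrt(3)."""
    st, _ = reference
    sigma = 0.5
    noisy = perturb(st, sigma, seed=3)
    rmsd, _, _ = superpose(st, noisy, atom="CA")
    assert abs(rmsd - sigma * np.sqrt(3)) / (sigma * np.sqrt(3)) < 0.1


# --- batch screening -------------------------------------------------------

def test_batch_report_order_errors_and_calls(tmp_path):
    paths = []
    specs = [MimicSpec(seed=1), MimicSpec(seed=2),
             MimicSpec(orientations=("up", "up", "up", "up")),
             MimicSpec(cxxc_sites=False)]
    for k, spec in enumerate(specs):
        st, truth = make_ist_mimic(spec)
        p = tmp_path / f"m{k}.pdb"
        write_with_sidecar(st, truth, p)
        paths.append(p)
    bad = tmp_path / "broken.pdb"
    bad.write_text("not a structure\n")
    paths.insert(2, bad)
    df = batch_report(paths)
    assert list(df["path"]) == [str(p) for p in paths]
    assert df.loc[2, "error"] != ""
    calls = [df.loc[i, "ist_call"] for i in (0, 1, 3, 4)]
    assert calls == [True, True, False, False]
    assert len(batch_report([])) == 0
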