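"""MSA conservation, solvent accessibility, surface patches."""
import io

import numpy as np
import pytest
from Bio import AlignIO

from conftest import random_rigid_motion
from istfold.conservation import (conservation_scores, find_patches,
                                  map_scores_to_structure, read_msa,
                                  relative_sasa)
from istfold.structure import Atom, Residue, Structure
from istfold.synth import synthetic_alignment, write_fasta


def _aln(rows):
    fasta = "".join(f">r{k}\n{s}\n" for k, s in enumerate(rows))
    return AlignIO.read(io.StringIO(fasta), "fasta")


def test_identical_rows_score_one():
    scores = conservation_scores(_aln(["ACDEF"] * 3))
    assert all(np.isclose(s.conservation, 1.0) for s in scores)
    assert [s.ref_seq_num for s in scores] == [1, 2, 3, 4, 5]


def test_gap_column_flagged():
    scores = conservation_scores(_aln(["A-C", "A-C", "A-C"]))
    assert scores[1].conservation is None
    assert scores[1].gap_fraction == 1.0
    # gap in the reference row: no mapped residue number
    assert scores[1].ref_seq_num is None
    assert scores[2].ref_seq_num == 2


def test_ragged_alignment_rejected(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">a\nACDE\n>b\nACD\n")
    with pytest.raises(ValueError, match="ragged"):
        read_msa(p)


def test_reference_row_lookup(tmp_path):
    p = tmp_path / "ok.fasta"
    p.write_text(">a\nACDE\n>b\nACDF\n")
    _, idx = read_msa(p, ref_id="b")
    assert idx == 1
    with pytest.raises(ValueError, match="not in alignment"):
        read_msa(p, ref_id="zz")


def test_score_monotone_in_column_concentration():
    """Columns sampled from a Dirichlet with higher concentration on one
    residue score higher on average (sampling oracle, fixed seed)."""
    rng = np.random.default_rng(7)
    aa = "ACDEFGHIKLMNPQRSTVWY"

    def sample_alignment(alpha_major):
        cols = []
        for _ in range(60):
            alpha = np.ones(20) * 0.5
            alpha[rng.integers(20)] = alpha_major
            p = rng.dirichlet(alpha)
            cols.append(rng.choice(list(aa), size=12, p=p))
        return ["".join(col[r] for col in cols) for r in range(12)]

    means = []
    for alpha_major in (1.0, 10.0, 100.0):
        scores = conservation_scores(_aln(sample_alignment(alpha_major)))
        means.append(np.mean([s.conservation for s in scores]))
    assert means[0] < means[1] < means[2]


def test_scores_independent_of_row_order():
    rows = ["ACDEF", "ACDFF", "AKDEF", "ACWEF"]
    a = [s.conservation for s in conservation_scores(_aln(rows))]
    b = [s.conservation for s in conservation_scores(_aln(rows[::-1]))]
    assert np.allclose(a, b)


def test_map_scores_uses_author_offset(reference):
    st, _ = reference
    rows = synthetic_alignment(st, conserved=set(), n_rows=3, seed=1)
    scores = conservation_scores(_aln([s for _, s in rows]), ref_offset=27)
    smap = map_scores_to_structure(scores, st)
    assert min(smap) == 27 and max(smap) == 246
    assert len(smap) == 220


# --- solvent accessibility -------------------------------------------------

def _gly(num, center):
    center = np.asarray(center, dtype=float)
    return Residue("A", num, "GLY", [
        Atom("N", "N", center + [-1.2, 0.3, 0.0]),
        Atom("CA", "C", center),
        Atom("C", "C", center + [1.2, 0.3, 0.0]),
        Atom("O", "O", center + [1.4, 1.5, 0.0])])


def test_isolated_residue_fully_exposed():
    st = Structure("one", [_gly(1, [0, 0, 0])])
    rsa = relative_sasa(st)
    assert rsa[1] >= 0.95


def test_buried_centre_of_dense_cluster():
    """A residue at the centre of a tight shell of neighbours loses
    nearly all its accessible surface."""
    rng = np.random.default_rng(0)
    residues = [_gly(1, [0, 0, 0])]
    num = 2
    # two shells of neighbouring residues
    for r in (4.0, 7.5):
        n = 30 if r < 5 else 60
        for _ in range(n):
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * r
            residues.append(_gly(num, v))
            num += 1
    st = Structure("cluster", residues)
    rsa = relative_sasa(st)
    assert rsa[1] < 0.1


def test_sasa_rotation_invariant(reference):
    st, _ = reference
    rsa = relative_sasa(st)
    R, t = random_rigid_motion(10)
    rsa2 = relative_sasa(st.transformed(R, t))
    a = np.array([rsa[k] for k in sorted(rsa)])
    b = np.array([rsa2[k] for k in sorted(rsa2)])
    # point-sampling noise only
    assert abs(a.sum() - b.sum()) / a.sum() < 0.005


# --- patches ---------------------------------------------------------------

def test_planted_patches_recovered():
    """Two conserved clusters planted on fully exposed helices 35 A apart
    come back as exactly two patches with the right memberships
    (Jaccard >= 0.8 across 10 seeds)."""
    from istfold.structure import Structure
    from istfold.synth import HelixSpec, _helix_fragment
    frags = [
        _helix_fragment(HelixSpec(20)),
        _helix_fragment(HelixSpec(20, origin=np.array([35.0, 0.0, 0.0]))),
    ]
    residues, num = [], 1
    for frag in frags:
        for r in frag:
            residues.append(Residue("A", num, "GLY",
                                    [Atom(k, k[0], p)
                                     for k, p in r["atoms"].items()]))
            num += 1
    st = Structure("twohelix", residues)
    cluster1 = set(range(5, 13))
    cluster2 = set(range(25, 33))
    rsa = relative_sasa(st)
    for seed in range(10):
        rows = synthetic_alignment(st, cluster1 | cluster2, seed=seed)
        scores = conservation_scores(_aln([s for _, s in rows]))
        smap = map_scores_to_structure(scores, st)
        patches = find_patches(smap, rsa, st)
        assert len(patches) == 2
        for planted in (cluster1, cluster2):
            best = max(patches, key=lambda p: len(set(p.residues) & planted))
            got = set(best.residues)
            j = len(got & planted) / len(got | planted)
            assert j >= 0.8, (seed, sorted(got), sorted(planted))


def test_zero_variance_scores_give_no_patches(reference):
    st, _ = reference
    rsa = relative_sasa(st)
    flat = {r.seq_num: 0.7 for r in st.chain("A")}
    assert find_patches(flat, rsa, st) == []


def test_patches_invariant_under_rigid_motion(reference):
    st, _ = reference
    rows = synthetic_alignment(st, set(range(212, 226)), seed=3)
    scores = conservation_scores(_aln([s for _, s in rows]), ref_offset=27)
    smap = map_scores_to_structure(scores, st)
    p1 = find_patches(smap, relative_sasa(st), st)
    R, t = random_rigid_motion(11)
    moved = st.transformed(R, t)
    rsa2 = relative_sasa(moved)
    smap2 = map_scores_to_structure(scores, moved)
    p2 = find_patches(smap2, rsa2, moved)
    assert [p.residues for p in p1] == [p.residues for p in p2]


def test_epitope_patch_on_reference(reference):
    """With conservation planted on the published epitope span and the
    disulfide network, some surface patch contains at least 5 residues
    from 212-225."""
    st, truth = reference
    conserved = (set(range(212, 226)) | set(range(147, 155))
                 | {c for pair in truth["disulfide_pairs"] for c in pair})
    rows = synthetic_alignment(st, conserved, seed=0)
    write = _aln([s for _, s in rows])
    scores = conservation_scores(write, ref_offset=27)
    smap = map_scores_to_structure(scores, st)
    patches = find_patches(smap, relative_sasa(st), st)
    assert patches
    epitope = set(range(212, 226))
    assert max(len(set(p.residues) & epitope) for p in patches) >= 5


def test_write_fasta_roundtrip(tmp_path, reference):
    st, _ = reference
    rows = synthetic_alignment(st, {27, 30}, n_rows=4, seed=2)
    p = write_fasta(rows, tmp_path / "aln.fasta")
    aln, ref_idx = read_msa(p, ref_id="reference")
    assert ref_idx == 0
    assert len(aln) == 4
    assert str(aln[0].seq) == rows[0][1]
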