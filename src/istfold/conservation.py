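"""MSA conservation scores, solvent accessibility, and surface patches.

Conservation is 1 minus the normalized Shannon entropy of each alignment
column over the 20 amino-acid alphabet (gaps excluded; columns with more
than 50% gaps are flagged and get no score) -- a deliberately simple,
reproducible stand-in for phylogeny-aware conservation rates.  Scores are
mapped onto a reference structure by ungapped position in the reference
alignment row against author numbering.

Solvent accessibility uses the Shrake-Rupley sphere-point algorithm and
is normalized to theoretical Gly-X-Gly maxima (Tien et al. 2013).
Surface patches are single-linkage clusters (CA distance threshold) of
residues that are both conserved (top quartile by default) and exposed.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio import AlignIO
from scipy.spatial import cKDTree

from ._geom import fibonacci_sphere
from .structure import Structure

__all__ = [
    "AlignmentColumnScore",
    "SurfacePatch",
    "read_msa",
    "conservation_scores",
    "map_scores_to_structure",
    "relative_sasa",
    "find_patches",
]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "P": 1.80, "SE": 1.90}
PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960
EXPOSURE_CUTOFF = 0.25
LINK_DISTANCE = 10.0
CONSERVATION_QUANTILE = 0.75
GAP_FLAG_FRACTION = 0.5

# theoretical maximum ASA (A^2), Gly-X-Gly, Tien et al. 2013
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass
class AlignmentColumnScore:
    column: int                 # 0-based alignment column
    ref_seq_num: int | None     # mapped author number on the reference
    conservation: float | None  # in [0, 1]; None when gap-flagged
    gap_fraction: float


@dataclasses.dataclass
class SurfacePatch:
    residues: list[int]         # author numbering, sorted
    mean_conservation: float
    mean_rsa: float
    diameter: float             # max CA-CA distance within the patch, A

    def __len__(self) -> int:
        return len(self.residues)


def read_msa(path: str | Path, ref_id: str | None = None):
    """Read a FASTA alignment; returns (alignment, reference row index)."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ValueError(f"ragged alignment: {exc}") from exc
    lengths = {len(rec.seq) for rec in aln}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    ref_idx = 0
    if ref_id is not None:
        for k, rec in enumerate(aln):
            if rec.id == ref_id:
                ref_idx = k
                break
        else:
            raise ValueError(f"reference id {ref_id!r} not in alignment")
    return aln, ref_idx


def conservation_scores(aln, ref_idx: int = 0,
                        ref_offset: int = 1) -> list[AlignmentColumnScore]:
    """Per-column conservation = 1 - normalized Shannon entropy.

    `ref_offset` is the author number of the first (ungapped) residue of
    the reference row.
    """
    ref = str(aln[ref_idx].seq).upper()
    n_rows = len(aln)
    scores = []
    ref_pos = 0
    for col in range(aln.get_alignment_length()):
        column = [str(rec.seq[col]).upper() for rec in aln]
        ref_num = None
        if ref[col] not in ("-", "."):
            ref_num = ref_offset + ref_pos
            ref_pos += 1
        gaps = sum(1 for c in column if c in ("-", "."))
        gap_frac = gaps / n_rows
        if gap_frac > GAP_FLAG_FRACTION:
            scores.append(AlignmentColumnScore(col, ref_num, None, gap_frac))
            continue
        counts = np.array([sum(1 for c in column if c == a) for a in AA20],
                          dtype=float)
        total = counts.sum()
        if total == 0:
            scores.append(AlignmentColumnScore(col, ref_num, None, gap_frac))
            continue
        p = counts[counts > 0] / total
        entropy = float(-(p * np.log(p)).sum())
        score = 1.0 - entropy / np.log(20.0)
        scores.append(AlignmentColumnScore(col, ref_num, score, gap_frac))
    return scores


def map_scores_to_structure(scores: list[AlignmentColumnScore],
                            s: Structure,
                            chain_id: str | None = None) -> dict[int, float]:
    """Author seq_num -> conservation for residues present in the chain."""
    chain_id = chain_id or s.chain_ids[0]
    present = {r.seq_num for r in s.chain(chain_id)}
    return {sc.ref_seq_num: sc.conservation for sc in scores
            if sc.ref_seq_num in present and sc.conservation is not None}


def relative_sasa(s: Structure, chain_id: str | None = None,
                  n_points: int = N_SPHERE_POINTS,
                  probe: float = PROBE_RADIUS) -> dict[int, float]:
    """Per-residue relative solvent accessibility (Shrake-Rupley).

    Absolute per-residue ASA divided by the residue type's theoretical
    maximum; values can exceed 1 slightly for very exposed termini.
    """
    chain_id = chain_id or s.chain_ids[0]
    atoms = []
    for r in s.residues():
        for a in r.atoms:
            if a.element.upper() == "H":
                continue
            radius = VDW_RADII.get(a.element.upper(), 1.7) + probe
            atoms.append((a.pos, radius, r.chain_id, r.seq_num))
    pos = np.array([a[0] for a in atoms])
    rad = np.array([a[1] for a in atoms])
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(pos)
    asa_by_res: dict[tuple[str, int], float] = {}
    max_r = rad.max()
    for i in range(len(atoms)):
        neighbours = [j for j in tree.query_ball_point(pos[i], rad[i] + max_r)
                      if j != i
                      and np.linalg.norm(pos[j] - pos[i]) < rad[i] + rad[j]]
        pts = pos[i] + rad[i] * sphere
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            accessible &= np.linalg.norm(pts - pos[j], axis=1) >= rad[j]
            if not accessible.any():
                break
        area = 4.0 * np.pi * rad[i] ** 2 * accessible.sum() / n_points
        key = (atoms[i][2], atoms[i][3])
        asa_by_res[key] = asa_by_res.get(key, 0.0) + area
    out = {}
    for r in s.chain(chain_id):
        asa = asa_by_res.get((r.chain_id, r.seq_num), 0.0)
        out[r.seq_num] = asa / MAX_ASA.get(r.res_name, 180.0)
    return out


def find_patches(scores: dict[int, float], rsa: dict[int, float],
                 s: Structure, chain_id: str | None = None,
                 conservation_quantile: float = CONSERVATION_QUANTILE,
                 exposure_cutoff: float = EXPOSURE_CUTOFF,
                 link_distance: float = LINK_DISTANCE,
                 min_size: int = 3) -> list[SurfacePatch]:
    """Single-linkage clusters of conserved, exposed residues, size-sorted."""
    chain_id = chain_id or s.chain_ids[0]
    vals = [v for v in scores.values()]
    if not vals:
        return []
    if np.ptp(vals) < 1e-12:
        return []   # no conservation signal, nothing stands out
    cutoff = float(np.quantile(vals, conservation_quantile))
    ca = {}
    for r in s.chain(chain_id):
        a = r.atom("CA")
        if a is not None:
            ca[r.seq_num] = a.pos
    qualify = [n for n, v in scores.items()
               if v >= cutoff and rsa.get(n, 0.0) >= exposure_cutoff
               and n in ca]
    if not qualify:
        return []
    pts = np.array([ca[n] for n in qualify])
    tree = cKDTree(pts)
    n = len(qualify)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in tree.query_pairs(link_distance):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    patches = []
    for members in groups.values():
        if len(members) < min_size:
            continue
        nums = sorted(qualify[i] for i in members)
        coords = np.array([ca[x] for x in nums])
        diam = 0.0
        if len(coords) > 1:
            diffs = coords[:, None, :] - coords[None, :, :]
            diam = float(np.sqrt((diffs ** 2).sum(-1)).max())
        patches.append(SurfacePatch(
            nums,
            float(np.mean([scores[x] for x in nums])),
            float(np.mean([rsa.get(x, 0.0) for x in nums])),
            diam))
    patches.sort(key=lambda p: -len(p))
    return patches
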