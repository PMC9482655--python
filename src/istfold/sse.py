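"""Hydrogen-bond based secondary-structure assignment.

Backbone amide hydrogens are rebuilt geometrically, hydrogen bonds are
scored with the Kabsch-Sander electrostatic energy, and per-residue labels
(H: alpha helix, G: 3-10 helix, E: strand, C: coil) are derived from
4-turn, 3-turn and bridge patterns.  Strand bridges feed a segment-level
pairing graph whose connected components are beta-sheets.

Conventions: helices need two consecutive turns and a minimum segment
length of 3; strands need a bridge partner and a minimum length of 2;
priority H > E > G > C.  Pi-helices are not assigned.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.spatial import cKDTree

from ._geom import unit
from .structure import Residue, Structure

__all__ = [
    "HBond",
    "Segment",
    "SSEAnnotation",
    "place_amide_hydrogens",
    "detect_hbonds",
    "assign_sse",
    "sheet_topology",
]

logger = logging.getLogger(__name__)

# Kabsch-Sander: E = q1*q2*f*(1/rON + 1/rCH - 1/rOH - 1/rCN), kcal/mol
KS_CONST = 0.084 * 332.0
HBOND_ENERGY_CUTOFF = -0.5
HELIX_MIN_LEN = 3
STRAND_MIN_LEN = 2


@dataclasses.dataclass(frozen=True)
class HBond:
    """Backbone N-H...O=C bond; donor/acceptor are chain residue indices."""
    donor: int
    acceptor: int
    energy: float


@dataclasses.dataclass
class Segment:
    kind: str          # H, G, E or C
    start: int         # author seq_num of first residue
    end: int           # author seq_num of last residue
    indices: list[int]  # chain residue indices

    def __len__(self) -> int:
        return len(self.indices)


@dataclasses.dataclass
class SSEAnnotation:
    chain_id: str
    seq_nums: list[int]
    labels: list[str]
    segments: list[Segment]
    bridges: list[tuple[int, int, str]]   # (i, j, "P"|"AP"), i < j
    sheets: list[list[int]]               # segment indices, bridge-adjacency order
    sheet_pairings: list[list[str]]       # per sheet, classification per adjacent pair

    def strand_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "E"]

    def helix_segments(self, kinds: str = "HG") -> list[Segment]:
        return [s for s in self.segments if s.kind in kinds]

    def segment_of(self, index: int) -> Segment | None:
        for s in self.segments:
            if s.indices[0] <= index <= s.indices[-1]:
                return s
        return None


def place_amide_hydrogens(s: Structure) -> Structure:
    """Add an amide H to every residue with a preceding peptide carbonyl.

    H sits 1.0 A from N along the in-plane direction opposite the bisector
    of C(i-1)-N(i) and CA(i)-N(i).  Prolines and chain-initial residues get
    no H; residues missing backbone atoms are skipped with a warning.
    """
    new_residues = []
    for chain_id in s.chain_ids:
        prev: Residue | None = None
        for r in s.chain(chain_id):
            atoms = [dataclasses.replace(a, pos=a.pos.copy()) for a in r.atoms]
            rr = Residue(r.chain_id, r.seq_num, r.res_name, atoms, r.ins_code)
            if prev is not None and r.res_name != "PRO" and rr.atom("H") is None:
                n, ca, c_prev = rr.atom("N"), rr.atom("CA"), prev.atom("C")
                if n is None or ca is None or c_prev is None:
                    warnings.warn(
                        f"missing backbone atoms at {r.chain_id}{r.seq_num}; "
                        "no amide H placed")
                else:
                    d = unit(unit(n.pos - c_prev.pos) + unit(n.pos - ca.pos))
                    from .structure import Atom
                    rr.atoms.append(Atom("H", "H", n.pos + d))
            new_residues.append(rr)
            prev = r
    return Structure(s.id, new_residues)


def detect_hbonds(s: Structure, chain_id: str,
                  energy_cutoff: float = HBOND_ENERGY_CUTOFF) -> list[HBond]:
    """Kabsch-Sander hydrogen bonds within one chain.

    Donors are amide N-H groups, acceptors carbonyl C=O groups; pairs
    closer than 2 positions in sequence are excluded and each donor keeps
    at most its two best-energy acceptors.
    """
    chain = s.chain(chain_id)
    donors, don_idx = [], []
    accept_c, accept_o, acc_idx = [], [], []
    for i, r in enumerate(chain):
        n, h = r.atom("N"), r.atom("H")
        if n is not None and h is not None:
            donors.append((n.pos, h.pos))
            don_idx.append(i)
        c, o = r.atom("C"), r.atom("O")
        if c is not None and o is not None:
            accept_c.append(c.pos)
            accept_o.append(o.pos)
            acc_idx.append(i)
    if not donors or not accept_c:
        return []
    accept_c = np.asarray(accept_c)
    accept_o = np.asarray(accept_o)
    tree = cKDTree(accept_c)
    bonds: list[HBond] = []
    for (n_pos, h_pos), i in zip(donors, don_idx):
        best: list[HBond] = []
        for k in tree.query_ball_point(n_pos, 7.0):
            j = acc_idx[k]
            if abs(i - j) < 2:
                continue
            r_on = np.linalg.norm(n_pos - accept_o[k])
            r_ch = np.linalg.norm(h_pos - accept_c[k])
            r_oh = np.linalg.norm(h_pos - accept_o[k])
            r_cn = np.linalg.norm(n_pos - accept_c[k])
            dmin = min(r_on, r_ch, r_oh, r_cn)
            if dmin < 0.05:
                raise ValueError(
                    f"near-zero interatomic distance between residues "
                    f"{chain[i].seq_num} and {chain[j].seq_num}: corrupt coordinates")
            # clamp to keep a single close contact from blowing up the sum
            e = KS_CONST * (1.0 / max(r_on, 0.5) + 1.0 / max(r_ch, 0.5)
                            - 1.0 / max(r_oh, 0.5) - 1.0 / max(r_cn, 0.5))
            e = max(e, -9.9)
            if e < energy_cutoff:
                best.append(HBond(i, j, float(e)))
        best.sort(key=lambda b: b.energy)
        bonds.extend(best[:2])
    return bonds


def _segments_from_labels(chain: list[Residue], labels: list[str]) -> list[Segment]:
    segments: list[Segment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append(Segment(labels[start], chain[start].seq_num,
                                    chain[i - 1].seq_num, list(range(start, i))))
            start = i
    return segments


def assign_sse(s: Structure, chain_id: str,
               energy_cutoff: float = HBOND_ENERGY_CUTOFF) -> SSEAnnotation:
    """Per-residue secondary structure labels for one chain."""
    if not any(r.atom("H") for r in s.chain(chain_id)):
        s = place_amide_hydrogens(s)
    chain = s.chain(chain_id)
    n = len(chain)
    bonds = detect_hbonds(s, chain_id, energy_cutoff)
    hb = {(b.donor, b.acceptor) for b in bonds}

    turn4 = [((i + 4, i) in hb) for i in range(n)]
    turn3 = [((i + 3, i) in hb) for i in range(n)]

    labels = ["C"] * n
    # alpha helix: two consecutive 4-turns
    for i in range(n - 1):
        if turn4[i] and turn4[i + 1]:
            for k in range(i + 1, min(i + 5, n)):
                labels[k] = "H"

    # bridges (Kabsch-Sander parallel/antiparallel patterns)
    bridges: list[tuple[int, int, str]] = []

    def Hb(d: int, a: int) -> bool:
        # out-of-range partners simply fail the pattern
        return (d, a) in hb

    for i in range(n):
        for j in range(i + 3, n):
            if (Hb(j, i - 1) and Hb(i + 1, j)) or (Hb(i, j - 1) and Hb(j + 1, i)):
                bridges.append((i, j, "P"))
            elif (Hb(i, j) and Hb(j, i)) or (Hb(j + 1, i - 1) and Hb(i + 1, j - 1)):
                bridges.append((i, j, "AP"))

    for i, j, _ in bridges:
        for k in (i, j):
            if labels[k] != "H":
                labels[k] = "E"

    # 3-10 helix: two consecutive 3-turns, never overriding H or E
    for i in range(n - 1):
        if turn3[i] and turn3[i + 1]:
            for k in range(i + 1, min(i + 4, n)):
                if labels[k] == "C":
                    labels[k] = "G"

    # beta-bulge closure: a single non-strand residue flanked by strand on
    # both sides stays part of the strand (Kabsch-Sander bulge treatment)
    for k in range(1, n - 1):
        if labels[k] in "CG" and labels[k - 1] == "E" and labels[k + 1] == "E":
            labels[k] = "E"

    # enforce minimum segment lengths
    for _ in range(2):
        segs = _segments_from_labels(chain, labels)
        for seg in segs:
            if seg.kind in "HG" and len(seg) < HELIX_MIN_LEN:
                for k in seg.indices:
                    labels[k] = "C"
            elif seg.kind == "E" and len(seg) < STRAND_MIN_LEN:
                for k in seg.indices:
                    labels[k] = "C"
    bridges = [(i, j, t) for i, j, t in bridges
               if labels[i] == "E" and labels[j] == "E"]
    segments = _segments_from_labels(chain, labels)

    ann = SSEAnnotation(chain_id, [r.seq_num for r in chain], labels,
                        segments, bridges, [], [])
    ann.sheets, ann.sheet_pairings = _build_sheets(ann)
    return ann


def _build_sheets(ann: SSEAnnotation) -> tuple[list[list[int]], list[list[str]]]:
    """Connected components of the strand-pairing graph, adjacency-ordered."""
    strand_ids = [k for k, seg in enumerate(ann.segments) if seg.kind == "E"]
    idx_to_seg: dict[int, int] = {}
    for k in strand_ids:
        for i in ann.segments[k].indices:
            idx_to_seg[i] = k
    # edge -> bridge type votes
    votes: dict[tuple[int, int], list[str]] = {}
    for i, j, t in ann.bridges:
        a, b = idx_to_seg.get(i), idx_to_seg.get(j)
        if a is None or b is None or a == b:
            continue
        key = (min(a, b), max(a, b))
        votes.setdefault(key, []).append(t)
    adj: dict[int, set[int]] = {k: set() for k in strand_ids}
    pair_type: dict[tuple[int, int], str] = {}
    for (a, b), ts in votes.items():
        if len(ts) < 2:
            # a lone bridge is an isolated-bridge contact, not a sheet
            # pairing (cf. the B state in Kabsch-Sander)
            continue
        adj[a].add(b)
        adj[b].add(a)
        pair_type[(a, b)] = max(set(ts), key=ts.count)

    seen: set[int] = set()
    sheets, pairings = [], []
    for k in strand_ids:
        if k in seen:
            continue
        comp = []
        stack = [k]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(adj[u] - seen)
        comp.sort()
        order = _order_strands(comp, adj)
        sheets.append(order)
        pairings.append([
            pair_type.get((min(a, b), max(a, b)), "?")
            for a, b in zip(order, order[1:])])
    return sheets, pairings


def _order_strands(comp: list[int], adj: dict[int, set[int]]) -> list[int]:
    """Order strands of one sheet along bridge adjacency (path walk)."""
    if len(comp) == 1:
        return list(comp)
    in_comp = set(comp)
    deg = {u: len(adj[u] & in_comp) for u in comp}
    start = min((u for u in comp if deg[u] == 1), default=min(comp))
    order = [start]
    visited = {start}
    while True:
        nxt = [v for v in sorted(adj[order[-1]] & in_comp) if v not in visited]
        if not nxt:
            break
        order.append(nxt[0])
        visited.add(nxt[0])
    # barrel or branched sheets: append anything unreached in index order
    order.extend(u for u in comp if u not in visited)
    return order


def sheet_topology(ann: SSEAnnotation) -> list[dict]:
    """Per-sheet ordered strand list with pairwise P/AP classification."""
    out = []
    for order, pairing in zip(ann.sheets, ann.sheet_pairings):
        out.append({
            "strands": [(ann.segments[k].start, ann.segments[k].end)
                        for k in order],
            "segment_indices": list(order),
            "pairings": list(pairing),
            "n_strands": len(order),
        })
    return out
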