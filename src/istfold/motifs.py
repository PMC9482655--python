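"""Disulfide bonds, CXXC motifs, beta-hairpins, and the dual-CXXC hallmark.

The hallmark of interest is two CXXC motifs cross-linked by two disulfide
bonds, with one motif on a short helix (the single-turn N-terminal helix
of the bundle's triangular face) and the other at or near the turn of a
beta-hairpin in the hinge.  Both the "straight" (first-to-first) and
"crossed" pairing patterns are accepted and the observed one is recorded.
"""
from __future__ import annotations

import dataclasses
import warnings
from itertools import combinations

import numpy as np

from .sse import SSEAnnotation
from .structure import Structure, chain_sequence

__all__ = [
    "DisulfideBond",
    "CxxcMotif",
    "DualCxxcEvidence",
    "find_disulfides",
    "find_cxxc",
    "find_hairpins",
    "dual_cxxc_hallmark",
]

SG_CUTOFF = 2.5          # A
HAIRPIN_MAX_LOOP = 5     # residues between the paired strands
SHORT_HELIX_MAX = 7      # residues, "small N-terminal helix"


@dataclasses.dataclass(frozen=True)
class DisulfideBond:
    cys_a: int            # author seq_num, cys_a < cys_b
    cys_b: int
    sg_distance: float

    def partners(self) -> tuple[int, int]:
        return self.cys_a, self.cys_b


@dataclasses.dataclass(frozen=True)
class CxxcMotif:
    start: int                      # author seq_num of the first Cys
    cys_positions: tuple[int, int]  # (start, start+3) in author numbering
    context: str = "?"              # SSE label at the motif


@dataclasses.dataclass
class DualCxxcEvidence:
    motif_1: CxxcMotif
    motif_2: CxxcMotif
    bonds: list[DisulfideBond]
    motif_1_on_short_helix: bool
    motif_2_on_hairpin: bool
    pattern: str                    # "straight" or "crossed"


def find_disulfides(s: Structure, cutoff: float = SG_CUTOFF,
                    chain_id: str | None = None) -> list[DisulfideBond]:
    """Disulfide bonds from SG-SG distances, greedy closest-first pairing.

    Each SG joins at most one bond; cysteines without an SG atom are
    skipped with a warning.
    """
    cys = []
    for r in s.residues(chain_id):
        if r.res_name != "CYS":
            continue
        sg = r.atom("SG")
        if sg is None:
            warnings.warn(f"CYS {r.chain_id}{r.seq_num} has no SG atom; skipped")
            continue
        cys.append((r.seq_num, sg.pos))
    pairs = []
    for (na, pa), (nb, pb) in combinations(cys, 2):
        d = float(np.linalg.norm(pa - pb))
        if d <= cutoff:
            pairs.append((d, na, nb))
    pairs.sort()
    used: set[int] = set()
    bonds = []
    for d, na, nb in pairs:
        if na in used or nb in used:
            continue
        used.update((na, nb))
        bonds.append(DisulfideBond(min(na, nb), max(na, nb), d))
    bonds.sort(key=lambda b: b.partners())
    return bonds


def find_cxxc(sequence: str, seq_nums: list[int] | None = None,
              labels: list[str] | None = None) -> list[CxxcMotif]:
    """All (possibly overlapping) C-x-x-C positions in a sequence."""
    if seq_nums is None:
        seq_nums = list(range(1, len(sequence) + 1))
    out = []
    for i in range(len(sequence) - 3):
        if sequence[i] == "C" and sequence[i + 3] == "C":
            ctx = labels[i] if labels is not None else "?"
            out.append(CxxcMotif(seq_nums[i], (seq_nums[i], seq_nums[i + 3]),
                                 ctx))
    return out


def find_cxxc_in_structure(s: Structure, chain_id: str,
                           ann: SSEAnnotation | None = None) -> list[CxxcMotif]:
    seq, nums = chain_sequence(s, chain_id)
    labels = ann.labels if ann is not None else None
    return find_cxxc(seq, nums, labels)


def find_hairpins(ann: SSEAnnotation,
                  max_loop: int = HAIRPIN_MAX_LOOP) -> list[dict]:
    """Beta-hairpins: sequence-adjacent antiparallel strand pairs whose
    connecting loop is at most `max_loop` residues."""
    strands = ann.strand_segments()
    seg_ids = {id(s): k for k, s in enumerate(ann.segments)}
    pair_class: dict[tuple[int, int], str] = {}
    for order, pairing in zip(ann.sheets, ann.sheet_pairings):
        for (a, b), t in zip(zip(order, order[1:]), pairing):
            pair_class[(min(a, b), max(a, b))] = t
    out = []
    for s1, s2 in zip(strands, strands[1:]):
        k1, k2 = seg_ids[id(s1)], seg_ids[id(s2)]
        t = pair_class.get((min(k1, k2), max(k1, k2)))
        if t != "AP":
            continue
        loop = s2.indices[0] - s1.indices[-1] - 1
        if loop > max_loop:
            continue
        out.append({"strands": (s1, s2),
                    "turn": (s1.end + 1, s2.start - 1),
                    "loop_length": loop})
    return out


def _motif_on_short_helix(motif: CxxcMotif, ann: SSEAnnotation,
                          short_max: int = SHORT_HELIX_MAX) -> bool:
    pos = {ann.seq_nums[i]: i for i in range(len(ann.seq_nums))}
    for num in range(motif.cys_positions[0], motif.cys_positions[1] + 1):
        i = pos.get(num)
        if i is None:
            continue
        seg = ann.segment_of(i)
        if seg is not None and seg.kind in "HG" and len(seg) <= short_max:
            return True
    return False


def _motif_near_hairpin_turn(motif: CxxcMotif, hairpins: list[dict],
                             slack: int = 2) -> bool:
    a, b = motif.cys_positions
    for hp in hairpins:
        lo, hi = hp["turn"]
        if a >= lo - slack and b <= hi + slack:
            return True
    return False


def dual_cxxc_hallmark(s: Structure, ann: SSEAnnotation,
                       motifs: list[CxxcMotif] | None = None,
                       bonds: list[DisulfideBond] | None = None,
                       short_helix_max: int = SHORT_HELIX_MAX,
                       max_loop: int = HAIRPIN_MAX_LOOP
                       ) -> DualCxxcEvidence | None:
    """Two CXXC motifs cross-linked by exactly two disulfides, one on a
    short helix and the other at a hairpin turn."""
    if motifs is None:
        motifs = find_cxxc_in_structure(s, ann.chain_id, ann)
    if bonds is None:
        bonds = find_disulfides(s, chain_id=ann.chain_id)
    hairpins = find_hairpins(ann, max_loop)
    bond_set = {b.partners(): b for b in bonds}
    for m1, m2 in combinations(motifs, 2):
        c1 = set(m1.cys_positions)
        c2 = set(m2.cys_positions)
        if c1 & c2:
            continue
        cross = [b for b in bond_set.values()
                 if (b.cys_a in c1 and b.cys_b in c2)
                 or (b.cys_a in c2 and b.cys_b in c1)]
        if len(cross) != 2:
            continue
        # orient: motif on short helix first, motif at hairpin second
        for first, second in ((m1, m2), (m2, m1)):
            on_helix = _motif_on_short_helix(first, ann, short_helix_max)
            on_hairpin = _motif_near_hairpin_turn(second, hairpins)
            if on_helix and on_hairpin:
                straight = any(
                    {b.cys_a, b.cys_b} == {first.cys_positions[0],
                                           second.cys_positions[0]}
                    for b in cross)
                return DualCxxcEvidence(first, second, sorted(
                    cross, key=lambda b: b.partners()), True, True,
                    "straight" if straight else "crossed")
    return None
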