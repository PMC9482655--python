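"""IST-superfamily hallmark classification and rigid-body superposition.

The superfamily call requires the three bundle hallmarks: (1) a four-helix
bundle whose adjacent pairs alternate parallel/antiparallel around the
packing cycle, (2) a triangular face formed by a short helix packed
perpendicularly across two bundle helices, and (3) a dual-CXXC motif pair
cross-linked by two disulfides between that short helix and a hinge
hairpin.  An Ig-like sandwich domain is reported but not required, since
several family members lack it.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import domains as dom
from . import helixgeom as hg
from . import motifs as mt
from .sse import SSEAnnotation, assign_sse
from .structure import Structure, read_structure

__all__ = ["HallmarkReport", "classify", "superpose", "batch_report"]

MIN_CLASSIFY_LEN = 40


@dataclasses.dataclass
class HallmarkReport:
    structure_id: str
    chain_id: str
    h1_alternating_4hb: bool
    h2_triangular_face: bool
    h3_dual_cxxc: bool
    has_ig_domain: bool
    ist_call: bool
    bundle: hg.BundleCandidate | None = None
    face: dict | None = None
    dual_cxxc: mt.DualCxxcEvidence | None = None
    sandwich: dom.SandwichReport | None = None
    partition: dom.DomainPartition | None = None
    bend_angle: float | None = None
    distortion: float | None = None
    n_helices: dict = dataclasses.field(default_factory=dict)
    n_strands: int = 0
    disulfides: list = dataclasses.field(default_factory=list)
    motifs: list = dataclasses.field(default_factory=list)
    notes: list[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "structure_id": self.structure_id,
            "chain_id": self.chain_id,
            "h1_alternating_4hb": self.h1_alternating_4hb,
            "h2_triangular_face": self.h2_triangular_face,
            "h3_dual_cxxc": self.h3_dual_cxxc,
            "has_ig_domain": self.has_ig_domain,
            "ist_call": self.ist_call,
            "topology": self.bundle.topology if self.bundle else None,
            "bend_angle": self.bend_angle,
            "distortion": self.distortion,
            "n_helices_alpha": self.n_helices.get("H"),
            "n_helices_with_310": self.n_helices.get("HG"),
            "n_strands": self.n_strands,
            "n_disulfides": len(self.disulfides),
            "disulfides": [b.partners() for b in self.disulfides],
            "cxxc_motifs": [m.cys_positions for m in self.motifs],
            "notes": list(self.notes),
        }


def classify(s: Structure, chain_id: str | None = None,
             config=None) -> HallmarkReport:
    """Run the full hallmark pipeline on one chain of a structure."""
    from .config import Config
    cfg = config or Config()
    if chain_id is None:
        chain_id = s.chain_ids[0]
    chain = s.chain(chain_id)
    if len(chain) < MIN_CLASSIFY_LEN:
        raise ValueError(
            f"chain {chain_id} too short to classify ({len(chain)} residues)")

    ann = assign_sse(s, chain_id, cfg.hbond_energy_cutoff)
    axes = hg.helix_axes(s, ann, kinds="H")
    bundles = hg.find_bundles(axes, cfg.axis_distance_max,
                              cfg.min_bundle_helix_len)
    bundle = bundles[0] if bundles else None
    h1 = bundle is not None and bundle.alternating

    face = None
    if bundle is not None:
        in_bundle = {id(h.segment) for h in bundle.helices}
        lo, hi = hg.SHORT_HELIX_RANGE
        short = [a for a in hg.helix_axes(s, ann, kinds="HG")
                 if id(a.segment) not in in_bundle
                 and lo <= len(a.segment) <= hi]
        face = hg.triangular_face(bundle, short, cfg.perp_window,
                                  cfg.perp_centroid_dist)
    h2 = face is not None

    bonds = mt.find_disulfides(s, cfg.sg_cutoff, chain_id)
    motifs = mt.find_cxxc_in_structure(s, chain_id, ann)
    dual = mt.dual_cxxc_hallmark(s, ann, motifs, bonds,
                                 cfg.short_helix_max, cfg.hairpin_max_loop)
    h3 = dual is not None

    part = dom.partition_domains(s, ann, cfg.window_width)
    sandwich = None
    has_ig = False
    bend = None
    if part.sandwich_domain is not None:
        sandwich = dom.ig_sandwich_check(s, ann, part.sandwich_domain)
        has_ig = sandwich.is_sandwich
        if part.helical_domain is not None:
            try:
                bend = dom.interdomain_bend(s, part)
            except ValueError:
                pass

    report = HallmarkReport(
        structure_id=s.id, chain_id=chain_id,
        h1_alternating_4hb=h1, h2_triangular_face=h2, h3_dual_cxxc=h3,
        has_ig_domain=has_ig, ist_call=h1 and h2 and h3,
        bundle=bundle, face=face, dual_cxxc=dual, sandwich=sandwich,
        partition=part, bend_angle=bend,
        distortion=hg.distortion_score(bundle) if bundle else None,
        n_helices={"H": len(ann.helix_segments("H")),
                   "G": len(ann.helix_segments("G")),
                   "HG": len(ann.helix_segments("HG"))},
        n_strands=len(ann.strand_segments()),
        disulfides=bonds, motifs=motifs)
    if not bundles:
        report.notes.append("no four-helix bundle candidate")
    return report


def superpose(a: Structure, b: Structure,
              selection: tuple[int, int] | None = None,
              atom: str = "CA",
              chain_a: str | None = None,
              chain_b: str | None = None) -> tuple[float, np.ndarray,
                                                   np.ndarray]:
    """Least-squares rigid superposition of b onto a by author numbering.

    Residues are matched 1:1 by seq_num within `selection` (inclusive
    range); returns (RMSD in A, rotation, translation) with the optimal
    transform mapping b's coordinates onto a (Kabsch).
    """
    chain_a = chain_a or a.chain_ids[0]
    chain_b = chain_b or b.chain_ids[0]

    def pick(st: Structure, cid: str) -> dict[int, np.ndarray]:
        out = {}
        for r in st.chain(cid):
            if selection and not (selection[0] <= r.seq_num <= selection[1]):
                continue
            at = r.atom(atom)
            if at is not None:
                out[r.seq_num] = at.pos
        return out

    pa, pb = pick(a, chain_a), pick(b, chain_b)
    common = sorted(set(pa) & set(pb))
    if len(common) < 3:
        missing_a = sorted(set(pb) - set(pa))[:10]
        missing_b = sorted(set(pa) - set(pb))[:10]
        raise ValueError(
            f"fewer than 3 common {atom} atoms; unmatched in first: "
            f"{missing_a}, unmatched in second: {missing_b}")
    X = np.array([pb[k] for k in common])   # moving
    Y = np.array([pa[k] for k in common])   # fixed
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = (X0 @ R.T) - Y0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(common)))
    return rmsd, R, t


def batch_report(paths: list[str | Path], config=None,
                 chain_id: str | None = None) -> pd.DataFrame:
    """Classify a batch of structure files; one row per input, input order.

    Per-file failures are recorded in the row's `error` column and never
    abort the batch.
    """
    rows = []
    for p in paths:
        row: dict[str, Any] = {"path": str(p)}
        try:
            st = read_structure(p)
            rep = classify(st, chain_id=chain_id, config=config)
            row.update(rep.to_dict())
            row["error"] = ""
        except Exception as exc:
            row["error"] = str(exc)
            row["ist_call"] = None
        rows.append(row)
    return pd.DataFrame(rows)
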