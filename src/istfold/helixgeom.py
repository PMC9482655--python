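"""Helix axis fitting, crossing angles, bundle detection and distortion.

Axes are fitted from sliding-window centroids of CA positions and oriented
N-to-C, so "parallel" (crossing angle < 90 deg) means co-directed chains.
A four-helix bundle is a 4-cycle in the axis-distance graph; its packing
order is the angular order of the helix midpoints about the shared
centroid, and the hallmark alternation test asks whether adjacent pairs
around that cycle alternate parallel / antiparallel.
"""
from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np

from ._geom import angle_deg, principal_axis, segment_segment_distance, unit
from .sse import Segment, SSEAnnotation
from .structure import Structure

__all__ = [
    "HelixAxis",
    "BundleCandidate",
    "fit_axis",
    "crossing_angle",
    "classify_orientation",
    "find_bundles",
    "triangular_face",
    "distortion_score",
]

AXIS_DISTANCE_MAX = 14.0        # A, bundle packing threshold
MIN_BUNDLE_HELIX_LEN = 7        # residues
PERP_WINDOW = (60.0, 120.0)     # deg, perpendicularity band
PERP_CENTROID_DIST = 12.0       # A, short helix to bundle-helix end region
SHORT_HELIX_RANGE = (3, 7)      # residues


@dataclasses.dataclass
class HelixAxis:
    segment: Segment | None
    anchor: np.ndarray            # point on the axis (centroid)
    direction: np.ndarray         # unit, N -> C
    local_points: np.ndarray      # sliding-window axis trace
    straightness: float           # end-to-end / arc length, in (0, 1]
    arc_length: float

    @property
    def start(self) -> np.ndarray:
        proj = (self.local_points - self.anchor) @ self.direction
        return self.anchor + proj.min() * self.direction

    @property
    def end(self) -> np.ndarray:
        proj = (self.local_points - self.anchor) @ self.direction
        return self.anchor + proj.max() * self.direction

    @property
    def centroid(self) -> np.ndarray:
        return self.local_points.mean(axis=0)


@dataclasses.dataclass
class BundleCandidate:
    helices: list[HelixAxis]      # cyclic packing order
    angles: list[float]           # crossing angle per adjacent pair (deg)
    distances: list[float]        # axis distance per adjacent pair (A)
    topology: list[str]           # "P"/"AP" per adjacent pair

    @property
    def alternating(self) -> bool:
        return self.topology in (["P", "AP", "P", "AP"],
                                 ["AP", "P", "AP", "P"])

    @property
    def mean_distance(self) -> float:
        return float(np.mean(self.distances))


def fit_axis(ca_coords: np.ndarray, segment: Segment | None = None) -> HelixAxis:
    """Fit a helix axis from CA coordinates (N-terminal first).

    Local axis points are centroids of sliding windows of 4 consecutive
    CA atoms; the global direction is their principal direction oriented
    N to C; straightness is end-to-end trace distance over trace arc
    length (1 for a perfectly straight helix).
    """
    ca = np.asarray(ca_coords, dtype=float)
    if len(ca) < 4:
        raise ValueError("need at least 4 CA atoms to fit a helix axis")
    local = np.array([ca[i:i + 4].mean(axis=0) for i in range(len(ca) - 3)])
    if len(local) == 1:
        # 4 residues: direction from terminal CA difference
        direction = unit(ca[-1] - ca[0])
        return HelixAxis(segment, local[0], direction, local, 1.0, 0.0)
    anchor, direction = principal_axis(local)
    if np.dot(local[-1] - local[0], direction) < 0:
        direction = -direction
    # window-4 centroids wobble slightly around the axis (a window is ~1.1
    # helical turns); average over one more turn before measuring curvature
    if len(local) >= 5:
        trace = np.array([local[i:i + 4].mean(axis=0)
                          for i in range(len(local) - 3)])
    else:
        trace = local
    arc = float(np.linalg.norm(np.diff(trace, axis=0), axis=1).sum())
    # straightness: chord over the two-leg path through the point of
    # largest deviation from the chord -- exactly 1 for a straight axis,
    # cos(kink/2) for a single kink
    # straightness = cos of half the direction change between the first
    # and last third of the axis trace: exactly 1 for a straight helix,
    # and equal to end-to-end distance over path length (chord over two
    # legs) for a helix kinked once in the middle
    if len(trace) < 4:
        straight = 1.0
    else:
        k = max(2, len(trace) // 3)
        d1 = trace[k - 1] - trace[0]
        d2 = trace[-1] - trace[-k]
        c = np.dot(d1, d2) / (np.linalg.norm(d1) * np.linalg.norm(d2))
        theta = np.arccos(np.clip(c, -1.0, 1.0))
        straight = float(np.cos(0.5 * theta))
    return HelixAxis(segment, anchor, direction, local, straight, arc)


def helix_axes(s: Structure, ann: SSEAnnotation,
               kinds: str = "H") -> list[HelixAxis]:
    """Fitted axes for all helical segments with at least 4 CA atoms."""
    chain = s.chain(ann.chain_id)
    axes = []
    for seg in ann.helix_segments(kinds):
        ca = [chain[i].atom("CA") for i in seg.indices]
        ca = np.array([a.pos for a in ca if a is not None])
        if len(ca) >= 4:
            axes.append(fit_axis(ca, seg))
    return axes


def crossing_angle(a: HelixAxis, b: HelixAxis) -> tuple[float, float]:
    """Crossing angle (deg, in [0, 180] using N->C directions) and the
    minimum distance between the finite axis segments (A)."""
    ang = angle_deg(a.direction, b.direction)
    dist = segment_segment_distance(a.start, a.end, b.start, b.end)
    return ang, dist


def classify_orientation(angle: float) -> str:
    """P below 90 deg, AP at or above (the 90 deg tie goes to AP)."""
    if not (0.0 <= angle <= 180.0):
        raise ValueError("angle must be in [0, 180] degrees")
    return "P" if angle < 90.0 else "AP"


def find_bundles(axes: list[HelixAxis],
                 axis_distance_max: float = AXIS_DISTANCE_MAX,
                 min_len: int = MIN_BUNDLE_HELIX_LEN) -> list[BundleCandidate]:
    """All 4-helix subsets whose axis-distance graph contains a 4-cycle.

    Candidates are ordered by compactness (mean adjacent axis distance).
    """
    eligible = [a for a in axes
                if a.segment is None or len(a.segment) >= min_len]
    if len(eligible) < 4:
        return []
    out = []
    for quad in combinations(range(len(eligible)), 4):
        hs = [eligible[k] for k in quad]
        dist = {}
        for i, j in combinations(range(4), 2):
            dist[(i, j)] = crossing_angle(hs[i], hs[j])[1]

        def d(i, j):
            return dist[(min(i, j), max(i, j))]

        order = _cyclic_packing_order(hs)
        pairs = list(zip(order, order[1:] + order[:1]))
        if all(d(i, j) < axis_distance_max for i, j in pairs):
            ordered = [hs[i] for i in order]
            angles, dists, topo = [], [], []
            for i, j in pairs:
                ang, dd = crossing_angle(hs[i], hs[j])
                angles.append(ang)
                dists.append(dd)
                topo.append(classify_orientation(ang))
            out.append(BundleCandidate(ordered, angles, dists, topo))
    out.sort(key=lambda b: b.mean_distance)
    return out


def _cyclic_packing_order(hs: list[HelixAxis]) -> list[int]:
    centers = np.array([h.centroid for h in hs])
    ref_dir = hs[0].direction
    mean_axis = unit(sum(h.direction * (1.0 if np.dot(h.direction, ref_dir)
                                        >= 0 else -1.0) for h in hs))
    centroid = centers.mean(axis=0)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, mean_axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = unit(ref - np.dot(ref, mean_axis) * mean_axis)
    e2 = np.cross(mean_axis, e1)
    ang = [np.arctan2(np.dot(c - centroid, e2), np.dot(c - centroid, e1))
           for c in centers]
    order = list(np.argsort(ang))
    k = order.index(0)
    return order[k:] + order[:k]


def triangular_face(bundle: BundleCandidate, short_helices: list[HelixAxis],
                    perp_window: tuple[float, float] = PERP_WINDOW,
                    centroid_dist_max: float = PERP_CENTROID_DIST
                    ) -> dict | None:
    """Detect a short helix packed perpendicularly across two bundle helices.

    Fires when a short helix (3-7 residues, outside the bundle) crosses at
    60-120 deg with at least two bundle helices and its centroid lies
    within `centroid_dist_max` of the terminal third of both their axes.
    """
    lo, hi = perp_window
    for cand in short_helices:
        hits = []
        for bh in bundle.helices:
            ang, _ = crossing_angle(cand, bh)
            if not (lo <= ang <= hi):
                continue
            # terminal thirds of the bundle helix axis
            start, end = bh.start, bh.end
            third = (end - start) / 3.0
            c = cand.centroid
            d_n = segment_segment_distance(start, start + third, c, c)
            d_c = segment_segment_distance(end - third, end, c, c)
            d = min(d_n, d_c)
            if d <= centroid_dist_max:
                hits.append((d, bh))
        if len(hits) >= 2:
            hits.sort(key=lambda t: t[0])
            return {"perp_helix": cand,
                    "bundle_helices": [h for _, h in hits[:2]]}
    return None


def distortion_score(bundle: BundleCandidate, n_heights: int = 3) -> float:
    """Packing irregularity: mean of (a) the coefficient of variation of
    the four adjacent inter-axis distances sampled at `n_heights` heights
    along the bundle, and (b) the mean helix non-straightness.

    Zero for a perfectly regular straight bundle; grows with uneven
    packing or curved helices.
    """
    # sample all helices at matching heights along the common bundle axis,
    # regardless of each helix's own N->C sense
    ref = bundle.helices[0].direction
    ends = []
    for h in bundle.helices:
        lo, hi = h.start, h.end
        if np.dot(hi - lo, ref) < 0:
            lo, hi = hi, lo
        ends.append((lo, hi))
    fracs = np.linspace(0.15, 0.85, n_heights)
    cvs = []
    for f in fracs:
        ds = []
        pts = [lo + f * (hi - lo) for lo, hi in ends]
        for pa, pb in zip(pts, pts[1:] + pts[:1]):
            ds.append(np.linalg.norm(pa - pb))
        ds = np.asarray(ds)
        if ds.mean() > 0:
            cvs.append(ds.std() / ds.mean())
    cv = float(np.mean(cvs)) if cvs else 0.0
    bend = float(np.mean([1.0 - h.straightness for h in bundle.helices]))
    return 0.5 * (cv + bend)
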