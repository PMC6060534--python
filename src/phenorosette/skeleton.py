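"""2D skeleton analysis of segmented inflorescences.

A segmented inflorescence is thinned to a one-pixel-wide, 8-connected
skeleton (loops are kept, not pruned), every skeleton pixel is classified by
its number of skeleton neighbors (<= 1 end, 2 slab, >= 3 junction),
adjacent junction pixels are clustered into "actual junctions", and slab
paths between endpoints/junctions are traced into branches.  Per plant the
nine descriptors used to predict fruit number are:

    n_branches, n_actual_junctions, n_end_pixels, n_junction_pixels,
    n_slab_pixels, avg_branch_length, n_triple_points, n_quadruple_points,
    max_branch_length

summed over all skeleton components of the plant.  Branch length uses the
diagonal-aware step metric (1 for orthogonal, sqrt(2) for diagonal steps).
A junction cluster's degree is the number of distinct branch stubs leaving
it (a loop attached to a cluster contributes two); clusters of degree 3 are
triple points, degree 4 quadruple points.  An isolated closed cycle counts
as one branch of its full circumference with no end pixels; an isolated
single pixel is an end pixel forming one zero-length branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _sk_thin

from .imaging import Calibration

logger = logging.getLogger(__name__)

__all__ = [
    "SkeletonSummary",
    "Branch",
    "JunctionCluster",
    "skeletonize",
    "classify_pixels",
    "cluster_junctions",
    "trace_branches",
    "summarize_skeleton",
    "DESCRIPTOR_COLUMNS",
]

DESCRIPTOR_COLUMNS = (
    "n_branches",
    "n_actual_junctions",
    "n_end_pixels",
    "n_junction_pixels",
    "n_slab_pixels",
    "avg_branch_length",
    "n_triple_points",
    "n_quadruple_points",
    "max_branch_length",
)

END, SLAB, JUNCTION = 1, 2, 3
_STRUCT8 = np.ones((3, 3), dtype=bool)
_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonSummary:
    """The nine per-plant skeleton descriptors (sums over components)."""

    n_branches: int = 0
    n_actual_junctions: int = 0
    n_end_pixels: int = 0
    n_junction_pixels: int = 0
    n_slab_pixels: int = 0
    avg_branch_length: float = 0.0
    n_triple_points: int = 0
    n_quadruple_points: int = 0
    max_branch_length: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class Branch:
    """A traced branch: pixel path and diagonal-aware length (px)."""

    pixels: list[tuple[int, int]]
    length: float
    is_cycle: bool = False


@dataclass
class JunctionCluster:
    """8-connected cluster of junction pixels; degree = incident stubs."""

    pixels: list[tuple[int, int]]
    degree: int = 0


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-px-wide skeleton, preserving topology
    (loops are kept).  An empty mask yields an empty skeleton."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    return _sk_thin(mask)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndi.convolve(skel.astype(int), kernel, mode="constant", cval=0)


def classify_pixels(skel: np.ndarray) -> np.ndarray:
    """Classify each skeleton pixel by its 8-neighbor count on the
    skeleton: <= 1 -> end, 2 -> slab, >= 3 -> junction.

    Returns an int array: 0 background, 1 end, 2 slab, 3 junction.
    """
    skel = np.asarray(skel, dtype=bool)
    counts = _neighbor_counts(skel)
    classes = np.zeros(skel.shape, dtype=np.uint8)
    classes[skel & (counts <= 1)] = END
    classes[skel & (counts == 2)] = SLAB
    classes[skel & (counts >= 3)] = JUNCTION
    return classes


def cluster_junctions(
    skel: np.ndarray, classes: Optional[np.ndarray] = None
) -> list[JunctionCluster]:
    """Merge 8-connected junction pixels into actual junctions and count
    each cluster's degree (distinct branch stubs, via branch tracing)."""
    if classes is None:
        classes = classify_pixels(skel)
    clusters, _ = _clusters_and_ids(classes)
    _trace(np.asarray(skel, dtype=bool), classes, clusters)
    return clusters


def _clusters_and_ids(
    classes: np.ndarray,
) -> tuple[list[JunctionCluster], np.ndarray]:
    """Label junction clusters; return them plus a map pixel -> cluster id
    (0 where not a junction pixel)."""
    jmask = classes == JUNCTION
    lab, n = ndi.label(jmask, structure=_STRUCT8)
    clusters = []
    for k in range(1, n + 1):
        ys, xs = np.nonzero(lab == k)
        clusters.append(
            JunctionCluster(pixels=list(zip(ys.tolist(), xs.tolist())))
        )
    return clusters, lab


def _step(p: tuple[int, int], q: tuple[int, int]) -> float:
    return np.sqrt(2.0) if (p[0] != q[0] and p[1] != q[1]) else 1.0


def _neighbors_on(
    skel: np.ndarray, p: tuple[int, int]
) -> list[tuple[int, int]]:
    h, w = skel.shape
    out = []
    for dy, dx in _NBRS:
        y, x = p[0] + dy, p[1] + dx
        if 0 <= y < h and 0 <= x < w and skel[y, x]:
            out.append((y, x))
    return out


def _trace(
    skel: np.ndarray,
    classes: np.ndarray,
    clusters: list[JunctionCluster],
) -> list[Branch]:
    """Trace all branches and fill in cluster degrees.

    Node pixels are end pixels and junction-cluster pixels.  Each slab path
    between two node pixels becomes one branch; node pixels directly
    adjacent across clusters (or end-junction, end-end) form zero-slab
    branches of a single step; leftover slab cycles touching no node are
    closed-loop branches.
    """
    _, cluster_ids = _clusters_and_ids(classes)
    for c in clusters:
        c.degree = 0

    def cluster_of(p: tuple[int, int]) -> int:
        return int(cluster_ids[p])

    def is_node(p: tuple[int, int]) -> bool:
        return classes[p] == END or classes[p] == JUNCTION

    branches: list[Branch] = []
    slab_visited = np.zeros_like(skel, dtype=bool)
    direct_edges: set[frozenset] = set()

    def register(start: tuple[int, int], end: tuple[int, int]) -> None:
        for p in (start, end):
            if classes[p] == JUNCTION:
                clusters[cluster_of(p) - 1].degree += 1

    node_pixels = [
        (int(p[0]), int(p[1]))
        for p in np.argwhere((classes == END) | (classes == JUNCTION))
    ]

    for p in node_pixels:
        nbrs = _neighbors_on(skel, p)
        if not nbrs and classes[p] == END:
            # isolated pixel: zero-length branch with one end
            branches.append(Branch(pixels=[p], length=0.0))
            continue
        for q in nbrs:
            if is_node(q):
                # direct node-node adjacency; skip within-cluster contacts
                if (
                    classes[p] == JUNCTION
                    and classes[q] == JUNCTION
                    and cluster_of(p) == cluster_of(q)
                ):
                    continue
                key = frozenset((p, q))
                if key in direct_edges:
                    continue
                direct_edges.add(key)
                branches.append(Branch(pixels=[p, q], length=_step(p, q)))
                register(p, q)
            else:  # slab: walk the path
                if slab_visited[q]:
                    continue
                path = [p, q]
                length = _step(p, q)
                slab_visited[q] = True
                prev, cur = p, q
                while True:
                    nxt = [r for r in _neighbors_on(skel, cur) if r != prev]
                    # prefer an unvisited slab or any node; a slab pixel has
                    # exactly 2 neighbors so nxt has at most 1 entry on
                    # clean skeletons
                    if not nxt:
                        break  # dangling slab (shouldn't happen when thin)
                    step_to = nxt[0]
                    if len(nxt) > 1:
                        nodes_n = [r for r in nxt if is_node(r)]
                        slabs_n = [
                            r
                            for r in nxt
                            if classes[r] == SLAB and not slab_visited[r]
                        ]
                        step_to = (nodes_n + slabs_n + nxt)[0]
                    length += _step(cur, step_to)
                    path.append(step_to)
                    if is_node(step_to):
                        break
                    if slab_visited[step_to]:
                        break  # closed back onto the path (cycle)
                    slab_visited[step_to] = True
                    prev, cur = cur, step_to
                branches.append(Branch(pixels=path, length=length))
                register(path[0], path[-1])

    # isolated cycles: slab pixels never visited and reachable from no node
    remaining = (classes == SLAB) & ~slab_visited
    lab, n = ndi.label(remaining, structure=_STRUCT8)
    for k in range(1, n + 1):
        ys, xs = np.nonzero(lab == k)
        start = (int(ys[0]), int(xs[0]))
        path = [start]
        slab_visited[start] = True
        length = 0.0
        prev, cur = None, start
        while True:
            nbrs = [r for r in _neighbors_on(skel, cur) if r != prev]
            nbrs = [r for r in nbrs if not slab_visited[r]] or nbrs
            if not nbrs:
                break
            nxt = nbrs[0]
            length += _step(cur, nxt)
            if nxt == start:
                path.append(nxt)
                break
            if slab_visited[nxt]:
                break
            path.append(nxt)
            slab_visited[nxt] = True
            prev, cur = cur, nxt
        branches.append(Branch(pixels=path, length=length, is_cycle=True))

    return branches


def trace_branches(
    skel: np.ndarray, classes: Optional[np.ndarray] = None
) -> list[Branch]:
    """Trace every branch of the skeleton (see module docstring for the
    length metric and loop conventions)."""
    skel = np.asarray(skel, dtype=bool)
    if classes is None:
        classes = classify_pixels(skel)
    clusters, _ = _clusters_and_ids(classes)
    return _trace(skel, classes, clusters)


def analyze_skeleton(
    skel: np.ndarray, calib: Optional[Calibration] = None
) -> SkeletonSummary:
    """Classify, cluster, trace and summarize one skeleton image."""
    skel = np.asarray(skel, dtype=bool)
    classes = classify_pixels(skel)
    clusters, _ = _clusters_and_ids(classes)
    branches = _trace(skel, classes, clusters)
    scale = 1.0 / calib.px_per_cm if calib is not None else 1.0
    lengths = [b.length * scale for b in branches]
    n_branches = len(branches)
    return SkeletonSummary(
        n_branches=n_branches,
        n_actual_junctions=len(clusters),
        n_end_pixels=int(np.count_nonzero(classes == END)),
        n_junction_pixels=int(np.count_nonzero(classes == JUNCTION)),
        n_slab_pixels=int(np.count_nonzero(classes == SLAB)),
        avg_branch_length=float(np.sum(lengths) / n_branches)
        if n_branches
        else 0.0,
        n_triple_points=sum(1 for c in clusters if c.degree == 3),
        n_quadruple_points=sum(1 for c in clusters if c.degree == 4),
        max_branch_length=float(max(lengths)) if lengths else 0.0,
    )


def summarize_skeleton(
    skels: Iterable[np.ndarray] | np.ndarray,
    calib: Optional[Calibration] = None,
) -> SkeletonSummary:
    """Summarize all skeleton components of one plant into the nine
    descriptors (field-wise sums; avg length = total length / branches).

    Accepts a single skeleton image or an iterable of them.  With no
    skeleton pixels at all, returns an all-zero summary with a warning.
    """
    if isinstance(skels, np.ndarray):
        skels = [skels]
    total = SkeletonSummary()
    total_length = 0.0
    any_pixels = False
    for skel in skels:
        skel = np.asarray(skel, dtype=bool)
        if not skel.any():
            continue
        any_pixels = True
        s = analyze_skeleton(skel, calib)
        total_length += s.avg_branch_length * s.n_branches
        total.n_branches += s.n_branches
        total.n_actual_junctions += s.n_actual_junctions
        total.n_end_pixels += s.n_end_pixels
        total.n_junction_pixels += s.n_junction_pixels
        total.n_slab_pixels += s.n_slab_pixels
        total.n_triple_points += s.n_triple_points
        total.n_quadruple_points += s.n_quadruple_points
        total.max_branch_length = max(
            total.max_branch_length, s.max_branch_length
        )
    if not any_pixels:
        logger.warning("no skeleton pixels; returning all-zero summary")
        return SkeletonSummary()
    if total.n_branches:
        total.avg_branch_length = total_length / total.n_branches
    return total
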