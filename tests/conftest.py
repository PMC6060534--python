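"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities with naive pure-Python
scans (neighbor counting, flood fill, edge counting) so that the package's
vectorized implementations are checked against something that shares no
code with them.
"""

from __future__ import annotations

import numpy as np
import pytest

NBRS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------- oracles
def oracle_neighbor_count(skel: np.ndarray, y: int, x: int) -> int:
    h, w = skel.shape
    return sum(
        1
        for dy, dx in NBRS8
        if 0 <= y + dy < h and 0 <= x + dx < w and skel[y + dy, x + dx]
    )


def oracle_classify(skel: np.ndarray) -> dict[str, set]:
    """Classify skeleton pixels by naive neighbor counting."""
    out = {"end": set(), "slab": set(), "junction": set()}
    for y, x in zip(*np.nonzero(skel)):
        n = oracle_neighbor_count(skel, y, x)
        key = "end" if n <= 1 else ("slab" if n == 2 else "junction")
        out[key].add((int(y), int(x)))
    return out


def oracle_components(mask: np.ndarray) -> list[set]:
    """8-connected components by BFS flood fill."""
    seen = set()
    comps = []
    pixels = {(int(y), int(x)) for y, x in zip(*np.nonzero(mask))}
    for start in sorted(pixels):
        if start in seen:
            continue
        queue, comp = [start], set()
        seen.add(start)
        while queue:
            y, x = queue.pop()
            comp.add((y, x))
            for dy, dx in NBRS8:
                p = (y + dy, x + dx)
                if p in pixels and p not in seen:
                    seen.add(p)
                    queue.append(p)
        comps.append(comp)
    return comps


def oracle_junction_clusters(skel: np.ndarray) -> list[set]:
    classes = oracle_classify(skel)
    jmask = np.zeros_like(skel, dtype=bool)
    for y, x in classes["junction"]:
        jmask[y, x] = True
    return oracle_components(jmask)


def oracle_stub_count(skel: np.ndarray, cluster: set) -> int:
    """Branch stubs leaving a junction cluster: connected components of the
    non-cluster skeleton pixels adjacent to it.  Valid on shapes whose
    stubs are mutually non-adjacent (lines, diagonal Y/X, drawn trees)."""
    adjacent = set()
    for y, x in cluster:
        for dy, dx in NBRS8:
            p = (y + dy, x + dx)
            if (
                p not in cluster
                and 0 <= p[0] < skel.shape[0]
                and 0 <= p[1] < skel.shape[1]
                and skel[p]
            ):
                adjacent.add(p)
    amask = np.zeros_like(skel, dtype=bool)
    for y, x in adjacent:
        amask[y, x] = True
    return len(oracle_components(amask))


def oracle_crack_perimeter(mask: np.ndarray) -> int:
    """Count foreground pixel edges facing background, one pixel at a time."""
    h, w = mask.shape
    edges = 0
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy, dx in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                    edges += 1
    return edges


# ---------------------------------------------------------------- shapes
def draw_y(arm: int = 20, size: int | None = None) -> np.ndarray:
    """Symmetric Y: vertical down-arm and two diagonal up-arms meeting at
    one pixel, each of `arm` pixels beyond the center."""
    size = size or (2 * arm + 21)
    c = size // 2
    img = np.zeros((size, size), dtype=bool)
    img[c, c] = True
    for k in range(1, arm + 1):
        img[c + k, c] = True
        img[c - k, c - k] = True
        img[c - k, c + k] = True
    return img


def draw_x(arm: int = 15) -> np.ndarray:
    size = 2 * arm + 11
    c = size // 2
    img = np.zeros((size, size), dtype=bool)
    for k in range(-arm, arm + 1):
        img[c + k, c + k] = True
        img[c + k, c - k] = True
    return img


def draw_line(n: int = 100, diagonal: bool = False) -> np.ndarray:
    if diagonal:
        img = np.zeros((n + 4, n + 4), dtype=bool)
        for k in range(n):
            img[2 + k, 2 + k] = True
    else:
        img = np.zeros((5, n + 4), dtype=bool)
        img[2, 2 : 2 + n] = True
    return img


def draw_ring(radius: int = 20) -> np.ndarray:
    """A thin digitized circle (already 1 px wide after thinning)."""
    size = 2 * radius + 11
    c = size // 2
    img = np.zeros((size, size), dtype=bool)
    for a in np.linspace(0, 2 * np.pi, 40 * radius, endpoint=False):
        img[int(round(c + radius * np.sin(a))), int(round(c + radius * np.cos(a)))] = True
    return img


@pytest.fixture
def shape_y():
    return draw_y()


@pytest.fixture
def shape_x():
    return draw_x()


@pytest.fixture
def shape_ring():
    from phenorosette.skeleton import skeletonize

    return skeletonize(draw_ring())
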