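"""Filament-network morphometry from 2D images.

Mirrors the skeleton-based proxy measures for microtubule morphology:
8-bit conversion and intensity thresholding, binary skeletonization,
skeleton-graph analysis (junctions, branches, branch lengths), and
watershed patch-area analysis.  A junction is a skeleton locus from
which three or more branches arise; 8-adjacent junction-candidate pixels
are merged and counted as one junction, since thick crossings thin into
clusters of high-degree pixels and the measure of interest is junctions,
not junction pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _skimage_skeletonize
from skimage.segmentation import watershed

#: spur branches shorter than this many pixels that terminate at an
#: endpoint are pruned before counting (thinning artifacts).
DEFAULT_PRUNE_PX = 3

#: watershed markers for patch splitting are connected plateaus of the
#: distance transform above this fraction of each component's maximum
#: depth; lobes separated by a shallow neck get distinct markers while
#: convex patches keep a single one.
DEFAULT_PATCH_SEED_RELATIVE_HEIGHT = 0.6

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
            (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Branch:
    """A maximal skeleton path between nodes (or a closed cycle)."""

    path: list[tuple[int, int]]
    length_um: float
    end_kinds: tuple[str, str]      # each of {junction, endpoint, cycle}

    @property
    def touches_endpoint(self) -> bool:
        return "endpoint" in self.end_kinds


@dataclass
class SkeletonGraph:
    """Pixel-level skeleton decomposition of one cell's filament network."""

    skeleton_pixels: set[tuple[int, int]]
    junction_pixels: set[tuple[int, int]]
    endpoints: set[tuple[int, int]]
    branches: list[Branch]
    n_junctions: int                # merged junction nodes, not pixels


@dataclass
class SkeletonSummary:
    """Per-cell morphometry: junction/branch counts, mean branch length,
    and watershed patch areas."""

    cell_id: str
    n_junctions: int
    n_branches: int
    mean_branch_length: float       # μm; 0 when there are no branches
    max_patch_area: float = 0.0     # μm²; headline patch column
    mean_patch_area: float = 0.0    # μm²; also emitted (see docs)


# ---------------------------------------------------------------------------
# thresholding / binarization
# ---------------------------------------------------------------------------

def binarize_filaments(image: np.ndarray, cell_mask: np.ndarray | None = None,
                       threshold: float | str = "otsu") -> np.ndarray:
    """Binarize a filament image inside the cell region.

    The image is first converted to 8-bit (min–max scaled over in-cell
    pixels), matching the conversion that precedes thresholding in the
    original workflow; then either Otsu's threshold (default) or a fixed
    8-bit value is applied.  A cell with no dynamic range yields an empty
    mask.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if cell_mask is None:
        cell_mask = np.ones(image.shape, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    values = image[cell_mask]
    if values.size == 0:
        return np.zeros(image.shape, dtype=bool)
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.zeros(image.shape, dtype=bool)
    img8 = np.clip(np.round((image - lo) / (hi - lo) * 255), 0, 255).astype(np.uint8)
    if threshold == "otsu":
        thr = threshold_otsu(img8[cell_mask])
    else:
        thr = float(threshold)
    return (img8 > thr) & cell_mask


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving 2D thinning to a 1-pixel-wide medial skeleton."""
    return _skimage_skeletonize(np.asarray(mask, dtype=bool))


# ---------------------------------------------------------------------------
# skeleton graph analysis
# ---------------------------------------------------------------------------

def _neighbors(p: tuple[int, int], pixels: set[tuple[int, int]]):
    y, x = p
    for dy, dx in _OFFSETS:
        q = (y + dy, x + dx)
        if q in pixels:
            yield q


def _step_length(p: tuple[int, int], q: tuple[int, int]) -> float:
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))   # 1 or √2


def _classify(pixels: set[tuple[int, int]]):
    degree = {p: sum(1 for _ in _neighbors(p, pixels)) for p in pixels}
    junction_px = {p for p, d in degree.items() if d >= 3}
    endpoints = {p for p, d in degree.items() if d == 1}
    return degree, junction_px, endpoints


def _junction_nodes(junction_px: set[tuple[int, int]]):
    """Merge 8-adjacent junction-candidate pixels into nodes."""
    node_of: dict[tuple[int, int], int] = {}
    n_nodes = 0
    for p in sorted(junction_px):
        if p in node_of:
            continue
        stack = [p]
        node_of[p] = n_nodes
        while stack:
            cur = stack.pop()
            for q in _neighbors(cur, junction_px):
                if q not in node_of:
                    node_of[q] = n_nodes
                    stack.append(q)
        n_nodes += 1
    return node_of, n_nodes


def _trace_branches(pixels: set[tuple[int, int]], pixel_size: float
                    ) -> tuple[list[Branch], int, set, set, dict]:
    degree, junction_px, endpoints = _classify(pixels)
    node_of, n_nodes = _junction_nodes(junction_px)
    is_node = lambda p: p in junction_px or p in endpoints  # noqa: E731

    branches: list[Branch] = []
    visited_slab: set[tuple[int, int]] = set()
    seen_node_edges: set[frozenset] = set()

    def kind_of(p):
        return "junction" if p in junction_px else "endpoint"

    for start in sorted(pixels):
        if not is_node(start):
            continue
        for nb in sorted(_neighbors(start, pixels)):
            if is_node(nb):
                if nb in junction_px and start in junction_px \
                        and node_of[nb] == node_of[start]:
                    continue            # internal to one junction cluster
                edge = frozenset((start, nb))
                if edge in seen_node_edges:
                    continue
                seen_node_edges.add(edge)
                branches.append(Branch([start, nb],
                                       _step_length(start, nb) * pixel_size,
                                       (kind_of(start), kind_of(nb))))
                continue
            if nb in visited_slab:
                continue
            # walk along degree-2 slab pixels
            path = [start, nb]
            length = _step_length(start, nb)
            visited_slab.add(nb)
            prev, cur = start, nb
            while True:
                nxt = None
                for q in sorted(_neighbors(cur, pixels)):
                    if q == prev:
                        continue
                    # avoid doubling back onto the start cluster corner
                    if q == start:
                        continue
                    nxt = q
                    break
                if nxt is None:
                    branches.append(Branch(path, length * pixel_size,
                                           (kind_of(start), "endpoint")))
                    break
                length += _step_length(cur, nxt)
                path.append(nxt)
                if is_node(nxt):
                    branches.append(Branch(path, length * pixel_size,
                                           (kind_of(start), kind_of(nxt))))
                    break
                visited_slab.add(nxt)
                prev, cur = cur, nxt

    # pure cycles: slab-only components never reached from a node
    for start in sorted(pixels):
        if is_node(start) or start in visited_slab:
            continue
        path = [start]
        visited_slab.add(start)
        length = 0.0
        prev, cur = None, start
        while True:
            nxt = None
            for q in sorted(_neighbors(cur, pixels)):
                if q != prev:
                    nxt = q
                    break
            if nxt is None:
                break                   # isolated pixel: no branch
            length += _step_length(cur, nxt)
            if nxt == start:
                branches.append(Branch(path, length * pixel_size,
                                       ("cycle", "cycle")))
                break
            path.append(nxt)
            visited_slab.add(nxt)
            prev, cur = cur, nxt
    return branches, n_nodes, junction_px, endpoints, node_of


def analyze_skeleton(skeleton: np.ndarray, pixel_size: float = 1.0,
                     prune_px: int = DEFAULT_PRUNE_PX) -> SkeletonGraph:
    """Decompose a skeleton into junctions, endpoints and branches.

    Skeleton pixels are classified by their 8-neighbour count (1 =
    endpoint, 2 = slab, ≥3 = junction candidate); adjacent junction
    candidates merge into single junction nodes.  Branches are maximal
    slab paths between nodes; branch length accumulates chamfer steps
    (1 × ``pixel_size`` orthogonal, √2 × ``pixel_size`` diagonal).  Spur
    branches shorter than ``prune_px`` pixels that terminate at an
    endpoint are removed and the graph re-derived until stable.
    """
    pixels = {tuple(p) for p in np.argwhere(np.asarray(skeleton, dtype=bool))}
    for _ in range(16):
        branches, n_nodes, junction_px, endpoints, node_of = \
            _trace_branches(pixels, pixel_size)
        if prune_px <= 0:
            break
        spurs = [b for b in branches
                 if b.touches_endpoint and b.length_um < prune_px * pixel_size]
        if not spurs:
            break
        removed = False
        for spur in spurs:
            # drop the spur's slab and endpoint pixels; keep junction pixels
            drop = [p for p, kind in zip(
                        (spur.path[0], spur.path[-1]),
                        spur.end_kinds) if kind == "endpoint"]
            drop += spur.path[1:-1]
            for p in drop:
                if p in pixels:
                    pixels.discard(p)
                    removed = True
        if not removed:
            break

    # Thinning can split one thick crossing into two junction clusters a
    # couple of pixels apart; contract junction-junction branches shorter
    # than the prune length, merging their nodes, so junctions are counted
    # as crossings rather than as thinning artifacts.
    if prune_px > 0 and n_nodes:
        parent = list(range(n_nodes))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        kept_branches = []
        for branch in branches:
            if branch.end_kinds == ("junction", "junction") \
                    and branch.length_um < prune_px * pixel_size:
                a = find(node_of[branch.path[0]])
                b = find(node_of[branch.path[-1]])
                if a != b:
                    parent[max(a, b)] = min(a, b)
                    continue           # contracted: nodes merged, branch gone
            kept_branches.append(branch)
        branches = kept_branches
        n_nodes = len({find(i) for i in range(n_nodes)})
    return SkeletonGraph(skeleton_pixels=pixels, junction_pixels=junction_px,
                         endpoints=endpoints, branches=branches,
                         n_junctions=n_nodes)


# ---------------------------------------------------------------------------
# patch analysis
# ---------------------------------------------------------------------------

def patch_areas(mask: np.ndarray, pixel_size: float,
                seed_relative_height: float = DEFAULT_PATCH_SEED_RELATIVE_HEIGHT
                ) -> list[float]:
    """Watershed patch areas (μm²) of a binary mask.

    Markers are distance-transform plateaus: per connected component,
    the connected regions where the Euclidean distance transform exceeds
    ``seed_relative_height`` × that component's maximum depth.  A convex
    patch keeps one marker (and stays whole); multi-lobed patches joined
    by shallow necks receive one marker per lobe and are split along the
    watershed of the inverted distance transform.  An empty mask yields
    an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    edt = ndimage.distance_transform_edt(mask, sampling=(pixel_size, pixel_size))
    comp_labels, n_comp = ndimage.label(mask, structure=_STRUCT_8)
    markers = np.zeros(mask.shape, dtype=np.int32)
    next_marker = 1
    for sl, comp_label in zip(ndimage.find_objects(comp_labels),
                              range(1, n_comp + 1)):
        comp = comp_labels[sl] == comp_label
        comp_edt = np.where(comp, edt[sl], 0.0)
        seed_region = comp_edt >= seed_relative_height * comp_edt.max()
        seed_labels, k = ndimage.label(seed_region, structure=_STRUCT_8)
        markers[sl][seed_region] = seed_labels[seed_region] + next_marker - 1
        next_marker += k
    if next_marker - 1 == n_comp:
        labels, n = comp_labels, n_comp       # no component needs splitting
    else:
        labels = watershed(-edt, markers=markers, mask=mask)
        n = next_marker - 1
    areas = ndimage.sum_labels(np.ones(mask.shape), labels,
                               index=range(1, n + 1))
    return [float(a) * pixel_size ** 2 for a in areas]


def max_patch_area(mask: np.ndarray, pixel_size: float,
                   seed_relative_height: float = DEFAULT_PATCH_SEED_RELATIVE_HEIGHT
                   ) -> float:
    """Maximum watershed patch area per cell, μm² (0 for an empty mask)."""
    areas = patch_areas(mask, pixel_size, seed_relative_height)
    return max(areas) if areas else 0.0


# ---------------------------------------------------------------------------
# per-cell pipeline
# ---------------------------------------------------------------------------

def summarize_cell(image: np.ndarray, pixel_size: float,
                   cell_mask: np.ndarray | None = None, cell_id: str = "",
                   threshold: float | str = "otsu",
                   prune_px: int = DEFAULT_PRUNE_PX) -> SkeletonSummary:
    """Binarize → skeletonize → analyze → patch areas for one cell."""
    mask = binarize_filaments(image, cell_mask, threshold)
    if not mask.any():
        return SkeletonSummary(cell_id, 0, 0, 0.0, 0.0, 0.0)
    graph = analyze_skeleton(skeletonize(mask), pixel_size, prune_px)
    lengths = [b.length_um for b in graph.branches]
    areas = patch_areas(mask, pixel_size)
    return SkeletonSummary(
        cell_id=cell_id,
        n_junctions=graph.n_junctions,
        n_branches=len(graph.branches),
        mean_branch_length=float(np.mean(lengths)) if lengths else 0.0,
        max_patch_area=max(areas) if areas else 0.0,
        mean_patch_area=float(np.mean(areas)) if areas else 0.0)
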