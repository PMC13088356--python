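"""Filament detection: segmentation, skeletonization, path extraction.

The DNA-backbone channel is thresholded into a binary mask, thinned to a
1-pixel-wide skeleton, and decomposed into a graph whose nodes are skeleton
endpoints/branch points and whose edges are ordered pixel chains.  Only
unambiguous single-filament stretches are analyzed: pixels near branch
points are pruned, and chains are filtered by arclength and local width
(twice the distance transform of the mask along the chain).  Surviving
paths are cut into equal-length fragments (default 1.5 µm) anchored at
arclength zero; the trailing remainder is discarded.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import skeletonize

from filamap.io_preprocess import ImageStack

#: default minimum component area: a disk of 0.5 µm diameter
DEFAULT_MIN_AREA_UM2 = np.pi * 0.25**2

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class FilamentPath:
    """Ordered, arc-length-parametrized centerline of one filament.

    ``points`` is an (N, 2) array of (x, y) in µm at pixel centers;
    ``cumulative_arclength`` is the running 8-connected chain length in µm,
    starting at 0; ``mean_width`` is the mean local mask width in µm.
    """

    path_id: int
    points: np.ndarray
    cumulative_arclength: np.ndarray
    mean_width: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.cumulative_arclength = np.asarray(self.cumulative_arclength, dtype=float)
        if len(self.points) < 2:
            raise ValueError("a filament path needs at least 2 points")
        dl = np.diff(self.cumulative_arclength)
        if self.cumulative_arclength[0] != 0 or np.any(dl <= 0):
            raise ValueError("cumulative arclength must start at 0 and increase")

    @property
    def arclength(self) -> float:
        return float(self.cumulative_arclength[-1])

    def position_at(self, s: float | np.ndarray) -> np.ndarray:
        """Interpolate (x, y) at arclength(s) ``s`` along the path."""
        s = np.atleast_1d(s)
        x = np.interp(s, self.cumulative_arclength, self.points[:, 0])
        y = np.interp(s, self.cumulative_arclength, self.points[:, 1])
        return np.column_stack([x, y])


@dataclass(frozen=True)
class FragmentSpec:
    """Half-open arclength window [start, end) on one path."""

    fragment_id: int
    path_id: int
    start_arclength: float
    end_arclength: float

    @property
    def length(self) -> float:
        return self.end_arclength - self.start_arclength


def segment_dna(
    stack: ImageStack,
    dna_channel: str,
    method: str = "otsu",
    threshold: float | None = None,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    smooth_sigma: float = 0.05,
) -> np.ndarray:
    """Segment the DNA-backbone channel into a boolean filament mask.

    ``method='otsu'`` uses Otsu's threshold on the (ideally
    background-corrected) channel; ``method='fixed'`` uses the given
    absolute intensity threshold.  The channel is smoothed with a Gaussian
    of ``smooth_sigma`` µm (default 0.05, about one PSF sigma) before
    thresholding so shot noise does not shred the mask boundary; set 0 to
    threshold raw intensities.  Connected components smaller than
    ``min_area_um2`` are removed.
    """
    img = stack.channel(dna_channel)
    if img.ndim != 2:
        raise ValueError("segment_dna expects a 2D stack (max-project first)")
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma / stack.pixel_size)
    if method == "otsu":
        if np.ptp(img) == 0:
            warnings.warn("segment_dna: constant image; returning empty mask")
            return np.zeros(img.shape, dtype=bool)
        thr = threshold_otsu(img)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold segmentation requires `threshold`")
        thr = threshold
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    mask = img > thr
    min_px = int(round(min_area_um2 / stack.pixel_size**2))
    if min_px > 1:
        labeled = label(mask, connectivity=2)
        sizes = np.bincount(labeled.ravel())
        small = np.flatnonzero(sizes < min_px)
        mask &= ~np.isin(labeled, small[small > 0])
    if not mask.any():
        warnings.warn("segment_dna: no foreground after filtering")
    return mask


def _chain_length_px(pixels: list[tuple[int, int]]) -> np.ndarray:
    """Cumulative 8-connected chain length (1 or √2 per step), in pixels."""
    if len(pixels) == 1:
        return np.zeros(1)
    arr = np.asarray(pixels, dtype=float)
    steps = np.hypot(*np.diff(arr, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(steps)])


def skeletonize_mask(mask: np.ndarray, pixel_size: float) -> nx.MultiGraph:
    """Thin a mask to a skeleton and decompose it into a chain graph.

    Nodes are (row, col) tuples of skeleton endpoints (degree 1) and branch
    points (degree ≥ 3); each edge carries the ordered pixel chain between
    its nodes in ``edge['pixels']`` (endpoints included) and its length in
    pixels in ``edge['length_px']``.  Isolated cycles are broken at an
    arbitrary pixel and stored as self-loop edges.  The pixel size and mask
    shape are recorded on ``graph.graph``.
    """
    mask = np.asarray(mask, dtype=bool)
    graph = nx.MultiGraph(pixel_size=pixel_size, shape=mask.shape)
    if not mask.any():
        return graph
    skel = skeletonize(mask)
    coords = set(zip(*np.nonzero(skel)))

    def nbrs(p):
        return [
            (p[0] + dy, p[1] + dx) for dy, dx in _NEIGHBORS8 if (p[0] + dy, p[1] + dx) in coords
        ]

    degree = {p: len(nbrs(p)) for p in coords}
    node_pixels = {p for p, d in degree.items() if d != 2}
    branch_pixels = {p for p, d in degree.items() if d >= 3}

    # 8-adjacent branch pixels belong to one junction: thinning renders a
    # crossing as a small clump of degree-≥3 pixels, not a single pixel
    cluster_rep: dict[tuple[int, int], tuple[int, int]] = {}
    for p in sorted(branch_pixels):
        if p in cluster_rep:
            continue
        stack_ = [p]
        members = []
        while stack_:
            q = stack_.pop()
            if q in cluster_rep:
                continue
            cluster_rep[q] = p  # provisional; fixed to min below
            members.append(q)
            stack_.extend(r for r in nbrs(q) if r in branch_pixels and r not in cluster_rep)
        rep = min(members)
        for q in members:
            cluster_rep[q] = rep

    def rep_of(p):
        return cluster_rep.get(p, p)

    graph.graph["junction_rep"] = dict(cluster_rep)

    visited_interior: set[tuple[int, int]] = set()
    direct_edges: set[tuple] = set()

    def trace(start, first):
        """Walk a chain from node `start` through `first` to the next node."""
        chain = [start, first]
        prev, cur = start, first
        while cur not in node_pixels:
            nxt = [q for q in nbrs(cur) if q != prev]
            if not nxt:
                break  # dead end inside chain (shouldn't happen)
            prev, cur = cur, nxt[0]
            chain.append(cur)
        return chain

    for node in sorted(node_pixels):
        for first in nbrs(node):
            if first in node_pixels:
                if rep_of(first) == rep_of(node):
                    continue  # internal adjacency within one junction clump
                key = (min(node, first), max(node, first))
                if key not in direct_edges:
                    direct_edges.add(key)
                    chain = [node, first]
                    graph.add_edge(
                        rep_of(node),
                        rep_of(first),
                        pixels=chain,
                        length_px=float(_chain_length_px(chain)[-1]),
                    )
                continue
            if first in visited_interior:
                continue
            chain = trace(node, first)
            visited_interior.update(p for p in chain if p not in node_pixels)
            graph.add_edge(
                rep_of(chain[0]),
                rep_of(chain[-1]),
                pixels=chain,
                length_px=float(_chain_length_px(chain)[-1]),
            )

    # isolated cycles: components made entirely of degree-2 pixels
    remaining = coords - visited_interior - node_pixels
    remaining = {p for p in remaining if degree[p] == 2}
    while remaining:
        start = min(remaining)
        chain = [start]
        prev, cur = None, start
        while True:
            options = [q for q in nbrs(cur) if q != prev and q in remaining]
            options = [q for q in options if q not in chain or q == start]
            if not options:
                break
            prev, cur = cur, options[0]
            if cur == start:
                chain.append(cur)
                break
            chain.append(cur)
        remaining -= set(chain)
        if len(chain) >= 2:
            graph.add_edge(
                chain[0],
                chain[-1],
                pixels=chain,
                length_px=float(_chain_length_px(chain)[-1]),
            )
    return graph


def _simplify_chains(
    items: list[tuple],
    pixel_size: float,
    spur_length: float,
) -> list[tuple]:
    """Drop short side-branches and merge chains through 2-way junctions.

    ``items`` are ``(u, v, pixels)`` triples where ``u``/``v`` are junction
    identities (cluster representatives) of the chain ends.  Skeletons of
    noisy masks carry short spurs off the main filament axis.  Iteratively:
    (1) remove chains shorter than ``spur_length`` (µm) that dangle from a
    junction (one free end, one junction end); (2) join the two chains
    meeting at any pure 2-way junction into one.  Repeats until stable,
    leaving maximal non-branching chains separated only at genuine ≥ 3-way
    junctions.
    """
    items = [(u, v, list(c)) for u, v, c in items if len(c) >= 2]
    changed = True
    while changed:
        changed = False
        incidence: dict[tuple[int, int], list[int]] = {}
        for i, (u, v, _) in enumerate(items):
            incidence.setdefault(u, []).append(i)
            incidence.setdefault(v, []).append(i)
        # 1) drop dangling spurs
        keep = []
        for i, (u, v, c) in enumerate(items):
            length = float(_chain_length_px(c)[-1]) * pixel_size
            d0, d1 = len(incidence[u]), len(incidence[v])
            is_spur = (
                length < spur_length
                and u != v
                and ((d0 == 1 and d1 >= 3) or (d1 == 1 and d0 >= 3))
            )
            if is_spur:
                changed = True
            else:
                keep.append((u, v, c))
        items = keep
        if changed:
            continue
        # 2) merge at pure 2-way junctions, one sweep per iteration
        incidence = {}
        for i, (u, v, _) in enumerate(items):
            incidence.setdefault(u, []).append(i)
            incidence.setdefault(v, []).append(i)
        consumed: set[int] = set()
        merged_out: list[tuple] = []
        for node, inc in incidence.items():
            if len(inc) != 2 or inc[0] == inc[1]:
                continue
            if inc[0] in consumed or inc[1] in consumed:
                continue
            ua, va, ca = items[inc[0]]
            ub, vb, cb = items[inc[1]]
            if va != node:
                ua, va, ca = va, ua, ca[::-1]
            if ub != node:
                ub, vb, cb = vb, ub, cb[::-1]
            joined = ca + (cb[1:] if ca[-1] == cb[0] else cb)
            merged_out.append((ua, vb, joined))
            consumed.update(inc)
            changed = True
        if changed:
            items = [it for i, it in enumerate(items) if i not in consumed] + merged_out
    return items


def extract_paths(
    skeleton: nx.MultiGraph,
    min_length: float,
    mask: np.ndarray,
    max_width: float,
    pruning_radius: float = 0.25,
    spur_length: float = 0.2,
    smoothing_sigma_px: float = 2.0,
) -> list[FilamentPath]:
    """Extract single non-branching filament paths from a skeleton graph.

    Short spurs (< ``spur_length`` µm) are removed and chains are merged
    through the 2-way junctions this leaves behind; chain pixels within
    ``pruning_radius`` (µm, arclength along the chain) of any remaining
    branch point (≥ 3-way junction) are then discarded, so only unambiguous
    single-filament stretches remain.  Surviving chains must have arclength
    ≥ ``min_length`` and mean local width ≤ ``max_width``, where local
    width = 2 × Euclidean distance transform of the mask evaluated along
    the chain.

    Path coordinates are smoothed along the chain (``smoothing_sigma_px``)
    before the arclength is accumulated: the raw 8-connected chain code
    overestimates arclength of oblique digital lines by several percent,
    which would inflate every downstream periodicity estimate.
    """
    if min_length <= 0 or max_width <= 0:
        raise ValueError("min_length and max_width must be > 0")
    pixel_size = skeleton.graph["pixel_size"]
    if skeleton.number_of_edges() == 0:
        return []
    dist = ndimage.distance_transform_edt(np.asarray(mask, dtype=bool))
    rep = skeleton.graph.get("junction_rep", {})
    items = [
        (rep.get(d["pixels"][0], d["pixels"][0]),
         rep.get(d["pixels"][-1], d["pixels"][-1]),
         d["pixels"])
        for _, _, d in skeleton.edges(data=True)
    ]
    items = _simplify_chains(items, pixel_size, spur_length)
    incidence: dict[tuple[int, int], int] = {}
    for u, v, _ in items:
        incidence[u] = incidence.get(u, 0) + 1
        incidence[v] = incidence.get(v, 0) + 1

    paths: list[FilamentPath] = []
    pid = itertools.count()
    for u, v, pixels in items:
        cum_px = _chain_length_px(pixels)
        lo, hi = 0, len(pixels)
        prune_px = pruning_radius / pixel_size
        if incidence[u] >= 3:
            lo = int(np.searchsorted(cum_px, prune_px, side="right"))
        if incidence[v] >= 3:
            hi = int(np.searchsorted(cum_px, cum_px[-1] - prune_px, side="left"))
        if hi - lo < 2:
            continue
        pixels = pixels[lo:hi]
        rows = np.array([p[0] for p in pixels])
        cols = np.array([p[1] for p in pixels])
        width = 2.0 * dist[rows, cols].mean() * pixel_size
        if width > max_width:
            continue
        pts = np.column_stack([(cols + 0.5) * pixel_size, (rows + 0.5) * pixel_size])
        if smoothing_sigma_px > 0 and len(pts) > 4:
            # de-zigzag the pixel chain: raw 8-connected chain code
            # overestimates the length of oblique lines by up to ~8%
            pts = np.column_stack(
                [
                    ndimage.gaussian_filter1d(pts[:, 0], smoothing_sigma_px, mode="nearest"),
                    ndimage.gaussian_filter1d(pts[:, 1], smoothing_sigma_px, mode="nearest"),
                ]
            )
        steps = np.hypot(*np.diff(pts, axis=0).T)
        good = steps > 1e-12  # drop coincident points created by smoothing
        keep_idx = np.concatenate([[True], good])
        pts = pts[keep_idx]
        steps = steps[good]
        if len(pts) < 2:
            continue
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        if cum[-1] < min_length:
            continue
        paths.append(
            FilamentPath(
                path_id=next(pid),
                points=pts,
                cumulative_arclength=cum,
                mean_width=float(width),
            )
        )
    return paths


def fragment_paths(
    paths: list[FilamentPath], fragment_length: float = 1.5
) -> list[FragmentSpec]:
    """Cut paths into contiguous fragments of exactly ``fragment_length`` µm.

    Per path, ``floor(arclength / fragment_length)`` fragments starting at
    arclength 0; the trailing remainder is discarded.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be > 0")
    fragments: list[FragmentSpec] = []
    fid = itertools.count()
    for path in paths:
        n = int(np.floor(path.arclength / fragment_length))
        for k in range(n):
            fragments.append(
                FragmentSpec(
                    fragment_id=next(fid),
                    path_id=path.path_id,
                    start_arclength=k * fragment_length,
                    end_arclength=(k + 1) * fragment_length,
                )
            )
    return fragments


def count_components(mask: np.ndarray) -> int:
    """Number of 8-connected foreground components in a mask."""
    return int(label(mask, connectivity=2).max())
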