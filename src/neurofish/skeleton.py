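"""Dendrite skeletons: 1-pixel midlines with geodesic distance from the soma.

The skeleton of a dendrite print is its morphological thinning (a single
1-px-wide 8-connected curve, possibly branched).  Distances "travelled
from the soma" are measured along this curve: the *anchor* is the skeleton
pixel closest (Euclidean) to the soma print, and every skeleton pixel gets
the shortest-path distance from the anchor on the 8-connected skeleton
graph, with axial steps costing one pixel pitch and diagonal steps √2
pitches.  Thinning of hand-annotated prints grows spurious short side
twigs; twigs shorter than ``prune_px`` are pruned before distances are
computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.morphology import skeletonize

from .geometry import GridGeometry
from .segmentation import CompartmentPrint

_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class DendriteSkeleton:
    """Midline of one dendrite with per-pixel geodesic distance (nm).

    ``pixels`` is an (n, 2) array of (row, col); ``geodesic_nm[i]`` is the
    along-skeleton distance of ``pixels[i]`` from the anchor.
    """

    dendrite_id: int
    pixels: np.ndarray  # (n, 2) int
    anchor: tuple[int, int]
    geodesic_nm: np.ndarray  # (n,) float
    degenerate: bool = False  # skeleton reduced to < 2 pixels

    def __post_init__(self) -> None:
        self._index = {tuple(p): i for i, p in enumerate(self.pixels)}

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def max_geodesic_nm(self) -> float:
        return float(self.geodesic_nm.max()) if len(self) else 0.0

    def distance_at(self, row: int, col: int) -> float:
        return float(self.geodesic_nm[self._index[(row, col)]])

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.pixels[:, 0], self.pixels[:, 1]] = True
        return out


def _adjacency(pixels: np.ndarray) -> dict[int, list[tuple[int, bool]]]:
    """8-neighbour adjacency among skeleton pixels; bool flags a diagonal."""
    index = {tuple(p): i for i, p in enumerate(pixels)}
    adj: dict[int, list[tuple[int, bool]]] = {i: [] for i in range(len(pixels))}
    for i, (r, c) in enumerate(pixels):
        for dr, dc in _EIGHT:
            j = index.get((r + dr, c + dc))
            if j is not None:
                adj[i].append((j, dr != 0 and dc != 0))
    return adj


def _prune_twigs(mask: np.ndarray, prune_px: int) -> np.ndarray:
    """Remove endpoint branches shorter than ``prune_px`` pixels.

    A twig runs from an endpoint (degree 1) to the first branch point
    (degree >= 3); only twigs hanging off a branch point are removed, so a
    simple unbranched path is never pruned away.
    """
    if prune_px <= 0:
        return mask
    mask = mask.copy()
    changed = True
    while changed:
        changed = False
        pixels = np.argwhere(mask)
        adj = _adjacency(pixels)
        degree = {i: len(adj[i]) for i in adj}
        for ep in [i for i, d in degree.items() if d == 1]:
            path = [ep]
            prev, cur = -1, ep
            while len(path) <= prune_px:
                nxt = [j for j, _ in adj[cur] if j != prev]
                if len(nxt) != 1:
                    break
                prev, cur = cur, nxt[0]
                if degree[cur] >= 3:
                    # twig ends at a branch point; drop it (keep the branch px)
                    for i in path:
                        mask[tuple(pixels[i])] = False
                    changed = True
                    break
                path.append(cur)
            if changed:
                break  # degrees changed; rebuild adjacency
    return mask


def skeletonize_print(
    dendrite_print: CompartmentPrint,
    soma_print: CompartmentPrint,
    geometry: GridGeometry,
    prune_px: int = 5,
) -> DendriteSkeleton:
    """Skeletonize a dendrite print and compute geodesic distances (nm).

    The anchor is the skeleton pixel with the smallest Euclidean distance
    to the soma print (ties broken by smallest (row, col)); distances are
    exact shortest paths on the 8-connected skeleton graph.

    Raises
    ------
    ValueError
        If the print is empty or not a single 8-connected component.
    """
    mask = dendrite_print.mask
    if not mask.any():
        raise ValueError("cannot skeletonize an empty dendrite print")
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        raise ValueError(f"dendrite print must be one connected component, found {n_comp}")

    skel = skeletonize(mask)
    skel = _prune_twigs(skel, prune_px)
    pixels = np.argwhere(skel)
    if len(pixels) == 0:  # print so small thinning left nothing; keep one pixel
        pixels = np.argwhere(mask)[:1]

    # anchor: skeleton pixel nearest the soma (Euclidean, in pixel units)
    dist_to_soma = ndimage.distance_transform_edt(~soma_print.mask)
    d = dist_to_soma[pixels[:, 0], pixels[:, 1]]
    candidates = np.flatnonzero(d == d.min())
    # ties -> smallest (row, col); argwhere already yields lexicographic order
    anchor_idx = int(candidates[0])
    anchor = (int(pixels[anchor_idx, 0]), int(pixels[anchor_idx, 1]))

    if len(pixels) < 2:
        return DendriteSkeleton(
            dendrite_id=dendrite_print.dendrite_id,
            pixels=pixels,
            anchor=anchor,
            geodesic_nm=np.zeros(len(pixels)),
            degenerate=True,
        )

    adj = _adjacency(pixels)
    rows, cols, weights = [], [], []
    p = geometry.pixel_size_xy
    for i, neighbours in adj.items():
        for j, diagonal in neighbours:
            rows.append(i)
            cols.append(j)
            weights.append(p * np.sqrt(2.0) if diagonal else p)
    graph = coo_matrix((weights, (rows, cols)), shape=(len(pixels), len(pixels)))
    geodesic = dijkstra(graph.tocsr(), directed=False, indices=anchor_idx)

    if not np.all(np.isfinite(geodesic)):
        # thinning of a connected mask is connected; guard anyway
        raise ValueError("skeleton is disconnected; geodesic distances undefined")

    return DendriteSkeleton(
        dendrite_id=dendrite_print.dendrite_id,
        pixels=pixels,
        anchor=anchor,
        geodesic_nm=geodesic,
    )


def skeletons_for(prints, geometry: GridGeometry, prune_px: int = 5) -> list[DendriteSkeleton]:
    """Skeletonize every dendrite print in a :class:`PrintSet`."""
    return [
        skeletonize_print(d, prints.soma, geometry, prune_px=prune_px) for d in prints.dendrites
    ]
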