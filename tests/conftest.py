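"""Shared fixtures: hand-built prints with known geometry, and small
random dendrite prints for oracle comparisons."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neurofish import GridGeometry, build_prints
from neurofish.segmentation import CompartmentPrint, PrintSet

PIX = 107.5


@pytest.fixture
def geometry():
    return GridGeometry(64, 64)


@pytest.fixture
def straight_printset():
    """Soma disk plus one straight horizontal dendrite of width 5.

    The dendrite occupies rows 29..33, cols 20..59; the soma is a disk of
    radius 8 centered at (31, 12), so the dendrite grows to the right of
    it and its skeleton is the row-31 midline.
    """
    soma = np.zeros((64, 64), dtype=bool)
    rr, cc = np.mgrid[0:64, 0:64]
    soma[(rr - 31) ** 2 + (cc - 12) ** 2 <= 8**2] = True
    nucleus = np.zeros_like(soma)
    nucleus[(rr - 31) ** 2 + (cc - 12) ** 2 <= 4**2] = True
    dend = np.zeros_like(soma)
    dend[29:34, 20:60] = True
    return build_prints(
        {"soma": soma, "nucleus": nucleus, "dendrite_1": dend}, closing_radius_px=0
    )


def spot_frame(coords_nm, species="rna1"):
    """Minimal spot table in the package schema from (x_nm, y_nm) tuples."""
    xs = [c[0] for c in coords_nm]
    ys = [c[1] for c in coords_nm]
    return pd.DataFrame(
        {
            "spot_id": np.arange(len(coords_nm), dtype=np.int64),
            "species": species,
            "x_nm": np.asarray(xs, dtype=float),
            "y_nm": np.asarray(ys, dtype=float),
            "z_nm": np.nan,
            "is_transcription_site": False,
            "nascent_count": np.nan,
        }
    )


def random_dendrite_print(rng: np.random.Generator, size: int = 50):
    """A small random ribbon print (single 8-connected component) plus a
    soma disk near the walk start, for geodesic oracle tests."""
    from skimage.draw import disk as draw_disk

    shape = (size, size)
    mask = np.zeros(shape, dtype=bool)
    pos = np.array([size / 2, size / 4], dtype=float)
    heading = rng.uniform(0, 2 * np.pi)
    width = rng.uniform(1.2, 2.2)
    for _ in range(rng.integers(20, 60)):
        heading += rng.normal(0, 0.5)
        nxt = pos + 1.5 * np.array([np.sin(heading), np.cos(heading)])
        if not (3 <= nxt[0] < size - 3 and 3 <= nxt[1] < size - 3):
            heading += np.pi / 2
            continue
        pos = nxt
        rr, cc = draw_disk(tuple(pos), width, shape=shape)
        mask[rr, cc] = True
    soma = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk((size / 2, size / 4), 4.0, shape=shape)
    soma[rr, cc] = True
    mask &= ~soma
    from scipy import ndimage

    labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return None
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    if mask.sum() < 8:
        return None
    return (
        CompartmentPrint("dendrite", mask, dendrite_id=1),
        CompartmentPrint("soma", soma),
    )


def networkx_geodesic(skel, geometry):
    """Independent Dijkstra oracle on the skeleton graph (networkx)."""
    import networkx as nx

    g = nx.Graph()
    pixset = {tuple(p) for p in skel.pixels}
    for r, c in skel.pixels:
        g.add_node((r, c))
    for r, c in skel.pixels:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                q = (r + dr, c + dc)
                if q in pixset:
                    w = geometry.pixel_size_xy * (np.sqrt(2.0) if dr and dc else 1.0)
                    g.add_edge((r, c), q, weight=w)
    return nx.single_source_dijkstra_path_length(g, skel.anchor)
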