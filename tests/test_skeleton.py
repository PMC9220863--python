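"""Skeletons: thinning, anchoring, and exact geodesic distances."""

import numpy as np
import pytest

from neurofish import GridGeometry, build_prints, skeletonize_print
from neurofish.segmentation import CompartmentPrint

from conftest import PIX, networkx_geodesic, random_dendrite_print


def _rect_printset(width_rows=3, cols=(16, 27)):
    soma = np.zeros((40, 40), dtype=bool)
    rr, cc = np.mgrid[0:40, 0:40]
    soma[(rr - 20) ** 2 + (cc - 8) ** 2 <= 5**2] = True
    dend = np.zeros((40, 40), dtype=bool)
    r0 = 20 - width_rows // 2
    dend[r0 : r0 + width_rows, cols[0] : cols[1]] = True
    return build_prints({"soma": soma, "dendrite_1": dend}, closing_radius_px=0)


def test_straight_line_print_gives_collinear_skeleton():
    """A 1-px-high solid rectangle is its own skeleton: a horizontal line
    whose farthest pixel sits (k-1) axial steps from the anchor."""
    prints = _rect_printset(width_rows=1)
    geom = GridGeometry(40, 40)
    sk = skeletonize_print(prints.dendrite(1), prints.soma, geom, prune_px=0)
    rows = {int(r) for r, c in sk.pixels}
    assert rows == {20}  # single midline row
    assert sk.geodesic_nm[np.argmin(sk.pixels[:, 1])] == 0.0  # anchor at the soma end
    k = len(sk)
    assert k == 11
    assert sk.max_geodesic_nm == pytest.approx((k - 1) * PIX)


def test_thick_rectangle_thins_to_one_pixel_midline():
    prints = _rect_printset(width_rows=3)
    geom = GridGeometry(40, 40)
    sk = skeletonize_print(prints.dendrite(1), prints.soma, geom, prune_px=0)
    # 1-px wide: one pixel per column, on or next to the midline row
    cols = [int(c) for _, c in sk.pixels]
    assert len(cols) == len(set(cols))
    assert all(abs(int(r) - 20) <= 1 for r, _ in sk.pixels)


def test_anchor_distance_is_zero_and_nearest_soma(geometry):
    prints = _rect_printset()
    sk = skeletonize_print(prints.dendrite(1), prints.soma, GridGeometry(40, 40))
    assert sk.distance_at(*sk.anchor) == 0.0
    # anchor is the leftmost skeleton pixel (closest to the soma disk)
    assert sk.anchor[1] == sk.pixels[:, 1].min()


def test_plus_shape_contains_branch_point():
    soma = np.zeros((48, 48), dtype=bool)
    soma[2:6, 2:6] = True
    plus = np.zeros((48, 48), dtype=bool)
    plus[22:27, 10:40] = True
    plus[10:40, 22:27] = True
    prints = build_prints({"soma": soma, "dendrite_1": plus}, closing_radius_px=0)
    sk = skeletonize_print(prints.dendrite(1), prints.soma, GridGeometry(48, 48), prune_px=0)
    pixset = {tuple(p) for p in sk.pixels}
    degrees = [
        sum(
            (r + dr, c + dc) in pixset
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        )
        for r, c in sk.pixels
    ]
    assert max(degrees) >= 3


def test_geodesic_matches_independent_dijkstra_on_random_prints():
    """Shortest-path distances agree with a networkx Dijkstra oracle to
    1e-9 relative error on random ribbon prints up to 50x50."""
    geom = GridGeometry(50, 50)
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 15:
        made = random_dendrite_print(rng)
        if made is None:
            continue
        dend, soma = made
        sk = skeletonize_print(dend, soma, geom, prune_px=0)
        if len(sk) < 2:
            continue
        oracle = networkx_geodesic(sk, geom)
        for (r, c), d in zip(sk.pixels, sk.geodesic_nm):
            assert d == pytest.approx(oracle[(int(r), int(c))], rel=1e-9)
        checked += 1


def test_skeletonization_is_idempotent():
    prints = _rect_printset()
    geom = GridGeometry(40, 40)
    sk1 = skeletonize_print(prints.dendrite(1), prints.soma, geom)
    line = CompartmentPrint("dendrite", sk1.mask((40, 40)), dendrite_id=1)
    sk2 = skeletonize_print(line, prints.soma, geom)
    assert {tuple(p) for p in sk1.pixels} == {tuple(p) for p in sk2.pixels}


def test_geodesics_invariant_under_translation_and_rotation():
    geom = GridGeometry(40, 40)
    prints = _rect_printset(width_rows=3)
    base = skeletonize_print(prints.dendrite(1), prints.soma, geom, prune_px=0)

    def dist_multiset(sk):
        return sorted(np.round(sk.geodesic_nm, 6).tolist())

    shift = (3, -5)
    shifted = skeletonize_print(
        CompartmentPrint("dendrite", np.roll(prints.dendrite(1).mask, shift, (0, 1)), 1),
        CompartmentPrint("soma", np.roll(prints.soma.mask, shift, (0, 1))),
        geom,
        prune_px=0,
    )
    assert dist_multiset(shifted) == dist_multiset(base)
    # thinning is orientation-sensitive only at the print's end pixels, so a
    # 90-degree rotation may gain/lose one terminal pixel; the geodesics of
    # the shared structure must agree exactly
    rot = skeletonize_print(
        CompartmentPrint("dendrite", np.rot90(prints.dendrite(1).mask), 1),
        CompartmentPrint("soma", np.rot90(prints.soma.mask)),
        geom,
        prune_px=0,
    )
    a, b = dist_multiset(base), dist_multiset(rot)
    assert abs(len(a) - len(b)) <= 1
    n = min(len(a), len(b))
    assert a[:n] == pytest.approx(b[:n])


def test_disconnected_print_is_rejected():
    soma = np.zeros((30, 30), dtype=bool)
    soma[0:4, 0:4] = True
    two = np.zeros((30, 30), dtype=bool)
    two[5:8, 5:15] = True
    two[20:23, 20:28] = True
    with pytest.raises(ValueError, match="connected"):
        skeletonize_print(
            CompartmentPrint("dendrite", two, dendrite_id=1),
            CompartmentPrint("soma", soma),
            GridGeometry(30, 30),
        )


def test_short_twigs_pruned_before_distances():
    soma = np.zeros((40, 40), dtype=bool)
    soma[18:22, 0:4] = True
    dend = np.zeros((40, 40), dtype=bool)
    dend[19:22, 6:36] = True
    dend[16:19, 20:23] = True  # small bump that thins to a short twig
    prints = build_prints({"soma": soma, "dendrite_1": dend}, closing_radius_px=0)
    geom = GridGeometry(40, 40)
    unpruned = skeletonize_print(prints.dendrite(1), prints.soma, geom, prune_px=0)
    assert min(int(r) for r, _ in unpruned.pixels) <= 17  # twig exists before pruning
    pruned = skeletonize_print(prints.dendrite(1), prints.soma, geom, prune_px=5)
    assert min(int(r) for r, _ in pruned.pixels) >= 19  # twig removed, midline kept
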