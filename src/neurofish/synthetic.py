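"""Synthetic fields of view with known localization ground truth.

A synthetic neuron is a filled soma disk (with a concentric nucleus)
from which non-self-intersecting random-walk ribbons of configurable
width grow outward as dendrites; synapse centroids sit on the ribbon
borders.  Spots are drawn with a configurable somatic fraction; dendritic
spots are placed along the dendrite midlines with density proportional to
``exp(-d/L)`` in geodesic distance ``d`` (``L = None`` gives placement
uniform over the dendrite prints, exactly matching the random-placement
null), optionally enriched near synapses and optionally duplicated as
close pairs to create colocalization structure.  Every spot carries its
true compartment, dendrite, geodesic distance and synapse association, so
each statistic in the package can be tested against known truth without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .geometry import GridGeometry
from .segmentation import DENDRITE, NUCLEUS, SOMA

DEFAULT_FOV_PX = 512


@dataclass(frozen=True)
class SyntheticTruth:
    """Localization structure the generator should bake into the spots.

    ``dendrite_decay_length_um = None`` places dendritic spots uniformly
    over the dendrite prints (no distance structure); a finite value
    concentrates them proximally with an exponential profile.
    ``synapse_enrichment`` is the multiple by which the fraction of
    dendritic spots within 500 nm of a synapse exceeds the uniform
    expectation; 1.0 means no enrichment.  ``pair_fraction`` of the spots
    are laid down as duplicated partners ``pair_distance_nm`` away.
    """

    somatic_fraction: float = 0.7
    dendrite_decay_length_um: float | None = 30.0
    synapse_enrichment: float = 1.0
    pair_fraction: float = 0.0
    pair_distance_nm: float = 200.0
    enrichment_radius_nm: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.somatic_fraction <= 1:
            raise ValueError("somatic_fraction must be in [0, 1]")
        if not 0 <= self.pair_fraction <= 1:
            raise ValueError("pair_fraction must be in [0, 1]")
        if self.synapse_enrichment < 1:
            raise ValueError("synapse_enrichment must be >= 1")


@dataclass
class SyntheticFov:
    """One generated field of view with full ground truth."""

    geometry: GridGeometry
    raw_masks: dict[str, np.ndarray]  # keys: nucleus, soma, dendrite_<k>
    spots: pd.DataFrame  # neurofish.io spot schema
    synapses: pd.DataFrame  # synapse_id, x_nm, y_nm
    truth: pd.DataFrame  # per-spot ground truth
    params: SyntheticTruth
    # per-dendrite midline ground truth: id -> (points (n,2) float px, cumlen_nm (n,))
    paths: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


TRUTH_COLUMNS = [
    "spot_id",
    "true_compartment",
    "true_dendrite_id",
    "true_geodesic_nm",
    "synapse_associated",
    "pair_id",
]


def _grow_dendrite(
    rng: np.random.Generator,
    center: np.ndarray,
    soma_radius: float,
    base_angle: float,
    shape: tuple[int, int],
    claimed: np.ndarray,
    width: float,
    step: float,
    min_len_px: float,
    heading_jitter: float = 0.06,
) -> np.ndarray | None:
    """Random-walk midline from the soma edge; returns (n,2) float (row,col)
    points or None when the walk collides before reaching ``min_len_px``."""
    margin = width + 2
    heading = base_angle + rng.normal(0, 0.15)
    point = center + (soma_radius - 1.0) * np.array([np.sin(heading), np.cos(heading)])
    points = [point.copy()]
    guard = width / 2 + 2  # clearance to other dendrites
    for _ in range(4000):
        heading += rng.normal(0, heading_jitter)
        # keep the walk within +-75 degrees of its radial direction so it
        # neither spirals back into the soma nor doubles over itself
        heading = base_angle + np.clip(heading - base_angle, -1.3, 1.3)
        nxt = point + step * np.array([np.sin(heading), np.cos(heading)])
        r, c = nxt
        if not (margin <= r < shape[0] - margin and margin <= c < shape[1] - margin):
            break
        if len(points) > 10 and np.linalg.norm(nxt - center) < soma_radius + 1:
            break  # walk curled back into the soma
        rr, cc = draw_disk((r, c), guard, shape=shape)
        if claimed[rr, cc].any():
            break
        point = nxt
        points.append(point.copy())
    path = np.asarray(points)
    if len(path) < 2 or (len(path) - 1) * step < min_len_px:
        return None
    return path


def _paint_ribbon(path: np.ndarray, radius: float, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r, c in path:
        rr, cc = draw_disk((r, c), radius, shape=shape)
        mask[rr, cc] = True
    return mask


def generate_synthetic_fov(
    n_spots: int = 400,
    n_dendrites: int = 5,
    n_synapses: int = 25,
    truth: SyntheticTruth | None = None,
    geometry: GridGeometry | None = None,
    soma_radius_px: float = 40.0,
    nucleus_radius_px: float = 20.0,
    dendrite_width_px: float = 7.0,
    min_dendrite_len_um: float | None = None,
    species: str = "rna1",
) -> SyntheticFov:
    """Generate masks, synapses and spots for one synthetic field of view.

    Dendrite midlines are random walks of 2-px steps leaving the soma in
    roughly evenly spread directions; walks stop at the image margin, at
    another dendrite, or back at the soma, and are retried when they stop
    too short.  Exactly ``n_spots`` spots are returned together with a
    per-spot truth table (:data:`TRUTH_COLUMNS`).
    """
    truth = truth or SyntheticTruth()
    geometry = geometry or GridGeometry(DEFAULT_FOV_PX, DEFAULT_FOV_PX)
    if n_spots < 0 or n_dendrites < 0 or n_synapses < 0:
        raise ValueError("counts must be >= 0")
    shape = geometry.shape
    if min(shape) < 4 * soma_radius_px:
        raise ValueError("geometry too small to host the requested soma and dendrites")
    rng = np.random.default_rng(truth.seed)
    p = geometry.pixel_size_xy
    step = 2.0
    half_w = dendrite_width_px / 2.0

    center = np.array([shape[0] / 2.0, shape[1] / 2.0])
    soma = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(tuple(center), soma_radius_px, shape=shape)
    soma[rr, cc] = True
    nucleus = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(tuple(center), nucleus_radius_px, shape=shape)
    nucleus[rr, cc] = True

    # --- dendrites -------------------------------------------------------
    claimed = np.zeros(shape, dtype=bool)
    raw_masks = {"soma": soma, "nucleus": nucleus}
    paths: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    dendrite_label = np.zeros(shape, dtype=np.int32)
    min_len = 12 * step if min_dendrite_len_um is None else min_dendrite_len_um * 1e3 / p
    for k in range(n_dendrites):
        base = 2 * np.pi * k / max(n_dendrites, 1)
        path = None
        for _ in range(12):
            path = _grow_dendrite(
                rng, center, soma_radius_px, base + rng.normal(0, 0.25),
                shape, claimed, dendrite_width_px, step, min_len,
            )
            if path is not None:
                break
        if path is None:
            continue
        did = len(paths) + 1
        ribbon = _paint_ribbon(path, half_w, shape)
        claimed |= _paint_ribbon(path, half_w + 2.5, shape)
        raw_masks[f"dendrite_{did}"] = ribbon
        dendrite_label[ribbon & (dendrite_label == 0)] = did
        cumlen = np.arange(len(path)) * step * p  # nm from the soma edge
        paths[did] = (path, cumlen)

    dendrite_union = dendrite_label > 0

    # --- synapses on the ribbon borders ---------------------------------
    syn_records = []
    eligible = [
        (did, i)
        for did, (path, cum) in paths.items()
        for i in range(len(path))
        if cum[i] >= (half_w + 3) * p
    ]
    for s in range(n_synapses if eligible else 0):
        did, i = eligible[rng.integers(0, len(eligible))]
        path, _ = paths[did]
        tangent = path[min(i + 1, len(path) - 1)] - path[max(i - 1, 0)]
        tangent = tangent / (np.linalg.norm(tangent) + 1e-12)
        perp = np.array([-tangent[1], tangent[0]]) * rng.choice([-1.0, 1.0])
        pos = path[i] + perp * half_w
        syn_records.append({"synapse_id": s, "x_nm": pos[1] * p, "y_nm": pos[0] * p})
    synapses = pd.DataFrame(syn_records, columns=["synapse_id", "x_nm", "y_nm"])

    # --- spots -----------------------------------------------------------
    n_som = int(round(truth.somatic_fraction * n_spots))
    n_den = n_spots - n_som
    n_pairs = int(round(truth.pair_fraction * n_spots / 2.0))
    n_pairs = min(n_pairs, n_den // 2)
    n_den_base = n_den - n_pairs
    if n_den and not paths:
        raise ValueError("dendritic spots requested but no dendrite could be grown")

    xs, ys = [], []
    t_comp, t_did, t_geo, t_syn, t_pair = [], [], [], [], []

    def record(x, y, comp, did, geo, syn_assoc, pair):
        xs.append(x)
        ys.append(y)
        t_comp.append(comp)
        t_did.append(did)
        t_geo.append(geo)
        t_syn.append(syn_assoc)
        t_pair.append(pair)

    # somatic spots: uniform over the soma print
    srows, scols = np.nonzero(soma)
    for _ in range(n_som):
        j = rng.integers(0, len(srows))
        x = (scols[j] + rng.random()) * p
        y = (srows[j] + rng.random()) * p
        comp = NUCLEUS if nucleus[srows[j], scols[j]] else SOMA
        record(x, y, comp, np.nan, np.nan, False, -1)

    # dendritic spots
    base_path_pt: list[np.ndarray | None] = []  # midline point of each dendritic base spot
    L_nm = None if truth.dendrite_decay_length_um is None else truth.dendrite_decay_length_um * 1e3
    if n_den_base:
        if L_nm is None:
            # structureless: uniform over the dendrite prints, like the null
            drows, dcols = np.nonzero(dendrite_union)
            for _ in range(n_den_base):
                j = rng.integers(0, len(drows))
                x = (dcols[j] + rng.random()) * p
                y = (drows[j] + rng.random()) * p
                did = int(dendrite_label[drows[j], dcols[j]])
                pts, cum = paths[did]
                q = np.array([y / p, x / p])
                i = int(np.argmin(np.sum((pts - q) ** 2, axis=1)))
                record(x, y, DENDRITE, did, float(cum[i]), False, -1)
                base_path_pt.append(pts[i])
        else:
            cand, weight = [], []
            for did, (pts, cum) in paths.items():
                ok = cum >= 1.0 * p  # just outside the soma junction
                for i in np.flatnonzero(ok):
                    cand.append((did, i))
                    weight.append(np.exp(-cum[i] / L_nm))
            weight = np.asarray(weight)
            weight = weight / weight.sum()
            choice = rng.choice(len(cand), size=n_den_base, p=weight)
            max_off = max(half_w - 1.5, 0.5)
            for ci in choice:
                did, i = cand[ci]
                pts, cum = paths[did]
                tangent = pts[min(i + 1, len(pts) - 1)] - pts[max(i - 1, 0)]
                tangent = tangent / (np.linalg.norm(tangent) + 1e-12)
                perp = np.array([-tangent[1], tangent[0]])
                # taper the transverse spread near the soma so junction spots
                # stay on the dendrite side of the boundary
                off_limit = min(max_off, max(0.0, cum[i] / p - 1.5))
                off = rng.uniform(-off_limit, off_limit)
                pos = pts[i] + perp * off
                record(pos[1] * p, pos[0] * p, DENDRITE, did, float(cum[i]), False, -1)
                base_path_pt.append(pts[i])

    # synapse enrichment: relocate a fraction of dendritic spots to within
    # the enrichment radius of a synapse so the near-synapse fraction is
    # `synapse_enrichment` times the uniform expectation
    if truth.synapse_enrichment > 1 and len(synapses) and n_den_base:
        drows, dcols = np.nonzero(dendrite_union)
        px_x = (dcols + 0.5) * p
        px_y = (drows + 0.5) * p
        sx = synapses["x_nm"].to_numpy()
        sy = synapses["y_nm"].to_numpy()
        d2 = (px_x[:, None] - sx[None, :]) ** 2 + (px_y[:, None] - sy[None, :]) ** 2
        near = d2.min(axis=1) <= truth.enrichment_radius_nm**2
        p0 = near.mean()
        rho = 0.0 if p0 >= 1 else min(1.0, (truth.synapse_enrichment - 1) * p0 / (1 - p0))
        near_rows, near_cols = drows[near], dcols[near]
        den_idx = [i for i in range(len(xs)) if t_comp[i] == DENDRITE]
        for i in den_idx:
            if rng.random() < rho and len(near_rows):
                j = rng.integers(0, len(near_rows))
                xs[i] = (near_cols[j] + rng.random()) * p
                ys[i] = (near_rows[j] + rng.random()) * p
                did = int(dendrite_label[near_rows[j], near_cols[j]])
                pts, cum = paths[did]
                q = np.array([ys[i] / p, xs[i] / p])
                k = int(np.argmin(np.sum((pts - q) ** 2, axis=1)))
                t_did[i] = did
                t_geo[i] = float(cum[k])
                t_syn[i] = True
                base_path_pt[i - n_som] = pts[k]

    # close pairs: duplicate dendritic base spots at pair_distance_nm
    if n_pairs:
        den_idx = [
            i for i in range(len(xs))
            if t_comp[i] == DENDRITE and base_path_pt[i - n_som] is not None
        ]
        chosen = rng.choice(den_idx, size=n_pairs, replace=False)
        for pair_id, i in enumerate(chosen):
            base = np.array([ys[i] / p, xs[i] / p])  # (row, col) px
            d_px = truth.pair_distance_nm / p
            placed = False
            angles = rng.uniform(0, 2 * np.pi, size=24)
            midline = base_path_pt[i - n_som]
            to_mid = midline - base
            fallback = np.arctan2(to_mid[0], to_mid[1]) if np.linalg.norm(to_mid) > 1e-9 else 0.0
            for ang in np.append(angles, fallback):
                q = base + d_px * np.array([np.sin(ang), np.cos(ang)])
                qr, qc = int(np.floor(q[0])), int(np.floor(q[1]))
                if 0 <= qr < shape[0] and 0 <= qc < shape[1] and dendrite_union[qr, qc]:
                    did = int(dendrite_label[qr, qc])
                    record(q[1] * p, q[0] * p, DENDRITE, did, t_geo[i], False, pair_id)
                    t_pair[i] = pair_id
                    placed = True
                    break
            if not placed:  # pair partner could not stay on the print
                record(xs[i], ys[i], DENDRITE, t_did[i], t_geo[i], False, pair_id)
                t_pair[i] = pair_id

    spots = pd.DataFrame(
        {
            "spot_id": np.arange(len(xs), dtype=np.int64),
            "species": species,
            "x_nm": np.asarray(xs, dtype=float),
            "y_nm": np.asarray(ys, dtype=float),
            "z_nm": np.nan,
            "is_transcription_site": False,
            "nascent_count": np.nan,
        }
    )
    truth_df = pd.DataFrame(
        {
            "spot_id": spots["spot_id"],
            "true_compartment": t_comp,
            "true_dendrite_id": t_did,
            "true_geodesic_nm": t_geo,
            "synapse_associated": t_syn,
            "pair_id": t_pair,
        }
    )
    return SyntheticFov(
        geometry=geometry,
        raw_masks=raw_masks,
        spots=spots,
        synapses=synapses,
        truth=truth_df,
        params=truth,
        paths=paths,
    )
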