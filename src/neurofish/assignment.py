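"""Assign each spot to a compartment and, for dendritic spots, a geodesic
distance from the soma.

A spot belongs to the compartment owning its pixel, with precedence
nucleus > soma > dendrite > unassigned (the nucleus print is a subset of
the soma print, so nuclear pixels must win over somatic ones).  A
dendritic spot inherits the geodesic distance of its nearest skeleton
pixel (Euclidean in nm between the spot and pixel centers, within its own
dendrite); the Euclidean spot→skeleton distance itself is reported as the
projection offset so thick prints and branch points can be audited.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import GridGeometry
from .segmentation import DENDRITE, NUCLEUS, PrintSet, SOMA, UNASSIGNED
from .skeleton import DendriteSkeleton

ASSIGNMENT_COLUMNS = [
    "spot_id",
    "species",
    "compartment",
    "dendrite_id",
    "geodesic_nm",
    "projection_offset_nm",
    "is_transcription_site",
    "nascent_count",
]


def assign_spots(
    spots: pd.DataFrame,
    prints: PrintSet,
    skeletons: list[DendriteSkeleton],
    geometry: GridGeometry,
    max_projection_offset_px: float = 20.0,
) -> pd.DataFrame:
    """Build the per-spot assignment table.

    Parameters
    ----------
    spots:
        Spot table (``neurofish.io.SPOT_COLUMNS`` schema).
    prints:
        Normalized prints (disjoint dendrites, nucleus within soma).
    skeletons:
        One :class:`DendriteSkeleton` per dendrite print.
    max_projection_offset_px:
        Dendritic spots farther than this from their skeleton are still
        assigned but trigger a warning (thick prints near branch points).

    Returns
    -------
    pandas.DataFrame
        One row per input spot (:data:`ASSIGNMENT_COLUMNS`); geodesic_nm
        and projection_offset_nm are NaN outside dendrites.
    """
    n = len(spots)
    row, col = geometry.to_pixel(spots["x_nm"].to_numpy(), spots["y_nm"].to_numpy())
    if np.any((row < 0) | (row >= geometry.height) | (col < 0) | (col >= geometry.width)):
        raise ValueError("spot coordinates fall outside the image grid; "
                         "load tables through neurofish.io to enforce bounds")

    compartment = np.full(n, UNASSIGNED, dtype=object)
    dendrite_id = np.full(n, np.nan)
    geodesic = np.full(n, np.nan)
    offset = np.full(n, np.nan)

    skel_by_id = {s.dendrite_id: s for s in skeletons}
    # precedence: dendrites first, then soma, then nucleus overwrite
    for dprint in prints.dendrites:
        hit = dprint.mask[row, col]
        compartment[hit] = DENDRITE
        dendrite_id[hit] = dprint.dendrite_id
    in_soma = prints.soma.mask[row, col]
    compartment[in_soma] = SOMA
    dendrite_id[in_soma] = np.nan
    if prints.nucleus is not None:
        in_nuc = prints.nucleus.mask[row, col]
        compartment[in_nuc] = NUCLEUS

    for did, skel in skel_by_id.items():
        sel = np.flatnonzero((compartment == DENDRITE) & (dendrite_id == did))
        if sel.size == 0 or len(skel) == 0:
            continue
        sx, sy = geometry.pixel_center_nm(skel.pixels[:, 0], skel.pixels[:, 1])
        tree = cKDTree(np.column_stack([sx, sy]))
        pts = np.column_stack([spots["x_nm"].to_numpy()[sel], spots["y_nm"].to_numpy()[sel]])
        k = min(4, len(skel))  # look at a few candidates to break distance ties
        dists, idx = tree.query(pts, k=k)
        dists = np.atleast_2d(dists.reshape(len(sel), k))
        idx = np.atleast_2d(idx.reshape(len(sel), k))
        for i in range(len(sel)):
            dmin = dists[i, 0]
            tied = idx[i, dists[i] <= dmin + 1e-9]
            best = tied[np.argmin(skel.geodesic_nm[tied])]  # ties -> smaller geodesic
            geodesic[sel[i]] = skel.geodesic_nm[best]
            offset[sel[i]] = dmin

    far = offset > max_projection_offset_px * geometry.pixel_size_xy
    if np.any(far):
        warnings.warn(
            f"{int(far.sum())} dendritic spot(s) farther than "
            f"{max_projection_offset_px} px from their skeleton; assigned anyway",
            stacklevel=2,
        )

    return pd.DataFrame(
        {
            "spot_id": spots["spot_id"].to_numpy(),
            "species": spots["species"].to_numpy(),
            "compartment": compartment,
            "dendrite_id": dendrite_id,
            "geodesic_nm": geodesic,
            "projection_offset_nm": offset,
            "is_transcription_site": spots["is_transcription_site"].to_numpy(),
            "nascent_count": spots["nascent_count"].to_numpy(),
        }
    )


def compartment_counts(assignment: pd.DataFrame) -> dict[str, int]:
    """Spot counts per compartment; values always sum to the table length."""
    counts = assignment["compartment"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in (NUCLEUS, SOMA, DENDRITE, UNASSIGNED)}
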