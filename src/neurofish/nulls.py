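"""Monte-Carlo random-placement null ensembles.

Both the synapse-occupancy and colocalization statistics are read against
the same reference: the observed number of molecules re-placed uniformly
at random on the dendritic shaft, many times.  A point is drawn by picking
a domain pixel uniformly and jittering it uniformly within the pixel, so
simulated coordinates have full sub-pixel (nm) resolution — the 500 nm
scales probed downstream are under five pixels.  The ensemble is entirely
determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GridGeometry
from .segmentation import DENDRITE, PrintSet


@dataclass
class NullEnsemble:
    """``n_sims`` simulated spot tables of matched size in a stated domain."""

    n_sims: int
    seed: int
    tables: list[pd.DataFrame]  # each with columns x_nm, y_nm
    domain_label: str = "dendrites"
    per_dendrite_matched: bool = False

    def __post_init__(self) -> None:
        if self.n_sims != len(self.tables):
            raise ValueError("n_sims does not match the number of tables")

    @property
    def n_points(self) -> int:
        return len(self.tables[0]) if self.tables else 0


def _draw_points(
    mask: np.ndarray, n: int, geometry: GridGeometry, rng: np.random.Generator
) -> pd.DataFrame:
    rows, cols = np.nonzero(mask)
    if len(rows) == 0 and n > 0:
        raise ValueError("cannot place points in an empty domain")
    idx = rng.integers(0, len(rows), size=n) if n > 0 else np.empty(0, dtype=int)
    jitter_x = rng.random(n)
    jitter_y = rng.random(n)
    p = geometry.pixel_size_xy
    return pd.DataFrame(
        {
            "x_nm": (cols[idx] + jitter_x) * p,
            "y_nm": (rows[idx] + jitter_y) * p,
        }
    )


def simulate_random_placement(
    n_points: int,
    domain_mask: np.ndarray,
    geometry: GridGeometry,
    n_sims: int,
    seed: int,
    domain_label: str = "dendrites",
) -> NullEnsemble:
    """Uniform random placement of ``n_points`` in a mask, ``n_sims`` times."""
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    tables = [_draw_points(domain_mask, n_points, geometry, rng) for _ in range(n_sims)]
    return NullEnsemble(n_sims=n_sims, seed=seed, tables=tables, domain_label=domain_label)


def simulate_matched_null(
    assignment: pd.DataFrame,
    prints: PrintSet,
    geometry: GridGeometry,
    n_sims: int,
    seed: int,
    per_dendrite: bool = True,
    species: str | None = None,
) -> NullEnsemble:
    """Null ensemble matched to the observed dendritic spots.

    With ``per_dendrite`` (default) each simulation preserves the observed
    per-dendrite spot counts, removing dendrite-size confounding; otherwise
    the global dendritic total is re-placed over the union of dendrite
    prints.
    """
    dend = assignment[assignment["compartment"] == DENDRITE]
    if species is not None:
        dend = dend[dend["species"] == species]
    rng = np.random.default_rng(seed)
    tables: list[pd.DataFrame] = []
    if per_dendrite:
        counts = {
            int(d): int(c) for d, c in dend["dendrite_id"].astype(int).value_counts().items()
        }
        masks = {d.dendrite_id: d.mask for d in prints.dendrites}
        for _ in range(n_sims):
            parts = [
                _draw_points(masks[did], c, geometry, rng)
                for did, c in sorted(counts.items())
                if did in masks
            ]
            tables.append(
                pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
                    {"x_nm": [], "y_nm": []}
                )
            )
    else:
        union = prints.dendrite_union()
        for _ in range(n_sims):
            tables.append(_draw_points(union, len(dend), geometry, rng))
    return NullEnsemble(
        n_sims=n_sims,
        seed=seed,
        tables=tables,
        per_dendrite_matched=per_dendrite,
    )
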