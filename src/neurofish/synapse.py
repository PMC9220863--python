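"""Synapse (dendritic spine) occupancy by mRNAs.

A molecule "localizes in a spine" when it lies within a fixed radius
(default 500 nm, a closed disk — a spot at exactly the radius counts) of
the synapse centroid marked by PSD95 immunofluorescence.  The statistic is
the percentage of synapses holding at least k molecules, k = 1..5,
compared against the random-placement null: the same number of molecules
re-placed uniformly on the dendritic shaft, 50 times by default, yielding
a null mean, SD and z-score per k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import GridGeometry
from .nulls import NullEnsemble
from .segmentation import PrintSet

DEFAULT_RADIUS_NM = 500.0
DEFAULT_K_MAX = 5

OCCUPANCY_COLUMNS = [
    "k",
    "observed_pct",
    "null_mean_pct",
    "null_sd_pct",
    "z_score",
    "n_synapses",
    "n_sims",
    "radius_nm",
]


@dataclass
class OccupancyResult:
    """Percent of synapses with >= k molecules within the radius."""

    table: pd.DataFrame  # OCCUPANCY_COLUMNS, one row per k
    n_synapses: int
    n_sims: int
    radius_nm: float
    seed: int | None = None
    n_synapses_flagged: int = 0  # centroids off the dendritic shaft

    def observed_pct(self, k: int) -> float:
        return float(self.table.set_index("k").loc[k, "observed_pct"])

    def z_score(self, k: int) -> float:
        return float(self.table.set_index("k").loc[k, "z_score"])


def _counts_within(
    spots_xy: np.ndarray, synapses_xy: np.ndarray, radius_nm: float
) -> np.ndarray:
    """Number of spots within the closed disk of each synapse."""
    if len(spots_xy) == 0:
        return np.zeros(len(synapses_xy), dtype=int)
    # pairwise distances; synapse counts are small enough for the dense form
    d2 = (
        (synapses_xy[:, None, 0] - spots_xy[None, :, 0]) ** 2
        + (synapses_xy[:, None, 1] - spots_xy[None, :, 1]) ** 2
    )
    return (d2 <= radius_nm**2 * (1 + 1e-12)).sum(axis=1)


def _occupancy_pct(counts: np.ndarray, k_max: int) -> np.ndarray:
    n = len(counts)
    return np.array([100.0 * (counts >= k).sum() / n for k in range(1, k_max + 1)])


def flag_off_shaft_synapses(
    synapses: pd.DataFrame,
    prints: PrintSet,
    geometry: GridGeometry,
    radius_nm: float = DEFAULT_RADIUS_NM,
) -> np.ndarray:
    """Boolean flag per synapse: centroid farther than ``radius_nm`` from
    every dendrite print (PSD95 detects spines that leave the shaft, so a
    tolerance of one radius is allowed before flagging)."""
    shaft = prints.dendrite_union()
    dist_px = ndimage.distance_transform_edt(~shaft)
    row, col = geometry.to_pixel(synapses["x_nm"].to_numpy(), synapses["y_nm"].to_numpy())
    row = np.clip(row, 0, geometry.height - 1)
    col = np.clip(col, 0, geometry.width - 1)
    return dist_px[row, col] * geometry.pixel_size_xy > radius_nm


def spine_occupancy(
    spots: pd.DataFrame,
    synapses: pd.DataFrame,
    null: NullEnsemble,
    radius_nm: float = DEFAULT_RADIUS_NM,
    k_max: int = DEFAULT_K_MAX,
) -> OccupancyResult:
    """Observed vs null spine occupancy.

    Parameters
    ----------
    spots:
        Dendritic spots (columns ``x_nm, y_nm``); distances to synapse
        centroids are 2D Euclidean in nm.
    synapses:
        Synapse centroids (columns ``x_nm, y_nm``).
    null:
        Matched random-placement ensemble; occupancy percentages are
        computed per simulation and then summarized (mean, SD).

    Notes
    -----
    ``z = (observed - null_mean) / null_sd``; when the null SD is zero the
    z-score is reported as NaN rather than ±inf.
    """
    if len(synapses) == 0:
        warnings.warn("no synapses in the field of view; empty occupancy result", stacklevel=2)
        return OccupancyResult(
            table=pd.DataFrame(columns=OCCUPANCY_COLUMNS),
            n_synapses=0,
            n_sims=null.n_sims,
            radius_nm=radius_nm,
            seed=null.seed,
        )
    syn_xy = synapses[["x_nm", "y_nm"]].to_numpy(dtype=float)
    obs_xy = spots[["x_nm", "y_nm"]].to_numpy(dtype=float)
    observed = _occupancy_pct(_counts_within(obs_xy, syn_xy, radius_nm), k_max)

    sim_pct = np.stack(
        [
            _occupancy_pct(
                _counts_within(t[["x_nm", "y_nm"]].to_numpy(dtype=float), syn_xy, radius_nm),
                k_max,
            )
            for t in null.tables
        ]
    )
    null_mean = sim_pct.mean(axis=0)
    null_sd = sim_pct.std(axis=0, ddof=1) if null.n_sims > 1 else np.zeros(k_max)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)

    table = pd.DataFrame(
        {
            "k": np.arange(1, k_max + 1),
            "observed_pct": observed,
            "null_mean_pct": null_mean,
            "null_sd_pct": null_sd,
            "z_score": z,
            "n_synapses": len(synapses),
            "n_sims": null.n_sims,
            "radius_nm": radius_nm,
        }
    )
    return OccupancyResult(
        table=table,
        n_synapses=len(synapses),
        n_sims=null.n_sims,
        radius_nm=radius_nm,
        seed=null.seed,
    )
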