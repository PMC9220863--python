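"""Compartment counts, per-pixel densities and log2 fold changes.

Because soma size varies strongly across development, absolute counts per
soma are complemented by densities normalized to the print area ("mRNAs
per pixel").  Mature single molecules and nascent transcripts at
transcription sites are tallied separately: the "soma" record pools
cytoplasmic somatic spots with nuclear single molecules, while
transcription-site records contribute only to the per-nucleus nascent
total.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

from .segmentation import DENDRITE, NUCLEUS, PrintSet, SOMA

DENSITY_COLUMNS = [
    "species",
    "compartment",
    "dendrite_id",
    "n_spots",
    "area_px",
    "density_px",
    "density_per_nm2",
]


class FoldChange(NamedTuple):
    """log2 fold change, or an explicit undefined marker (never ±inf)."""

    value: float | None
    defined: bool
    reason: str | None = None


def log2_fold_change(density_a: float, density_b: float) -> FoldChange:
    """``log2(density_a / density_b)``; undefined when either density is 0."""
    if density_a < 0 or density_b < 0:
        raise ValueError("densities must be nonnegative")
    if density_a == 0 and density_b == 0:
        return FoldChange(None, False, "both densities are zero")
    if density_b == 0:
        return FoldChange(None, False, "reference density is zero")
    if density_a == 0:
        return FoldChange(None, False, "numerator density is zero")
    return FoldChange(math.log2(density_a / density_b), True)


def compartment_density(
    assignment: pd.DataFrame,
    prints: PrintSet,
    pixel_size_nm: float,
    nuclear_singles_in_soma: bool = True,
) -> pd.DataFrame:
    """Per-(species, compartment) counts and densities.

    Dendrites are reported individually (``compartment='dendrite'`` with
    the dendrite id) and pooled (``'dendrites_pooled'``).  Transcription-
    site records are excluded everywhere here — see
    :func:`nascent_per_nucleus`.  With ``nuclear_singles_in_soma`` (the
    default) nuclear single molecules count toward the soma record, whose
    area is the full soma print (the nucleus print is a subset of it); a
    separate nucleus record is emitted as well.
    """
    mature = assignment[~assignment["is_transcription_site"].astype(bool)]
    records: list[dict] = []
    px_area_nm2 = pixel_size_nm**2

    def add(species: str, compartment: str, dendrite_id, n_spots: int, area_px: int) -> None:
        if area_px <= 0:
            raise ValueError(f"compartment {compartment!r} has zero area")
        density = n_spots / area_px
        records.append(
            {
                "species": species,
                "compartment": compartment,
                "dendrite_id": dendrite_id,
                "n_spots": int(n_spots),
                "area_px": int(area_px),
                "density_px": density,
                "density_per_nm2": density / px_area_nm2,
            }
        )

    soma_area = prints.soma.area_px
    nuc_area = prints.nucleus.area_px if prints.nucleus is not None else 0
    for species, group in mature.groupby("species", sort=True):
        comp = group["compartment"]
        n_nuc = int((comp == NUCLEUS).sum())
        n_soma_only = int((comp == SOMA).sum())
        n_soma = n_soma_only + (n_nuc if nuclear_singles_in_soma else 0)
        add(species, SOMA, None, n_soma, soma_area)
        if nuc_area:
            add(species, NUCLEUS, None, n_nuc, nuc_area)
        pooled_n = 0
        pooled_area = 0
        for dprint in prints.dendrites:
            n_d = int(((comp == DENDRITE) & (group["dendrite_id"] == dprint.dendrite_id)).sum())
            add(species, DENDRITE, dprint.dendrite_id, n_d, dprint.area_px)
            pooled_n += n_d
            pooled_area += dprint.area_px
        if pooled_area:
            add(species, "dendrites_pooled", None, pooled_n, pooled_area)

    if not records:
        return pd.DataFrame(columns=DENSITY_COLUMNS)
    return pd.DataFrame.from_records(records)[DENSITY_COLUMNS]


def nascent_per_nucleus(assignment: pd.DataFrame) -> pd.DataFrame:
    """Total nascent transcripts per species, summed over transcription
    sites assigned to the nucleus print."""
    ts = assignment[
        assignment["is_transcription_site"].astype(bool)
        & (assignment["compartment"] == NUCLEUS)
    ]
    records = []
    for species, group in ts.groupby("species", sort=True):
        records.append(
            {
                "species": species,
                "n_transcription_sites": int(len(group)),
                "nascent_total": float(np.nansum(group["nascent_count"].to_numpy(dtype=float))),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["species", "n_transcription_sites", "nascent_total"]
    )


def fold_change_table(density: pd.DataFrame, species_a: str, species_b: str) -> pd.DataFrame:
    """log2(density of ``species_a`` / ``species_b``) per compartment record."""
    key = ["compartment", "dendrite_id"]
    a = density[density["species"] == species_a].set_index(key)["density_px"]
    b = density[density["species"] == species_b].set_index(key)["density_px"]
    rows = []
    for idx in a.index.intersection(b.index):
        fc = log2_fold_change(float(a[idx]), float(b[idx]))
        rows.append(
            {
                "compartment": idx[0],
                "dendrite_id": idx[1],
                "log2_fold_change": fc.value if fc.defined else np.nan,
                "defined": fc.defined,
                "reason": fc.reason or "",
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["compartment", "dendrite_id", "log2_fold_change", "defined", "reason"]
    )
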