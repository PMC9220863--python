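"""Readers and writers for every external artifact.

Spot and synapse tables are plain :class:`pandas.DataFrame` objects with a
fixed schema (see :data:`SPOT_COLUMNS` / :data:`SYNAPSE_COLUMNS`); mask
images are boolean :class:`numpy.ndarray` stacks keyed by compartment
label.  Two spot-table dialects are understood:

``generic_csv``
    columns ``species, x_nm, y_nm`` and optionally ``z_nm, is_ts,
    nascent``; coordinates in nm.

``fishquant_csv``
    a FISH-Quant-style export whose position columns are named ``Pos_X``,
    ``Pos_Y`` (and optionally ``Pos_Z``).  Coordinate units default to nm
    (the FISH-Quant convention) but may be declared as pixels, in which
    case they are converted with the grid geometry on load.

Rows whose coordinates fall outside the field of view (or cannot be
parsed as numbers) never abort a load: they are returned in a per-row
rejection report alongside the clean table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .geometry import GridGeometry

SCHEMA_VERSION = "1"

#: canonical spot-table schema after load
SPOT_COLUMNS = [
    "spot_id",
    "species",
    "x_nm",
    "y_nm",
    "z_nm",
    "is_transcription_site",
    "nascent_count",
]

SYNAPSE_COLUMNS = ["synapse_id", "x_nm", "y_nm"]

_FISHQUANT_ALIASES = {"pos_x": "x_nm", "pos_y": "y_nm", "pos_z": "z_nm"}


@dataclass
class SpotTableLoad:
    """Result of a spot-table load: the clean table plus rejected rows."""

    spots: pd.DataFrame
    rejected: pd.DataFrame  # original row index, reason

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _empty_spots() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spot_id": pd.Series(dtype=np.int64),
            "species": pd.Series(dtype=object),
            "x_nm": pd.Series(dtype=float),
            "y_nm": pd.Series(dtype=float),
            "z_nm": pd.Series(dtype=float),
            "is_transcription_site": pd.Series(dtype=bool),
            "nascent_count": pd.Series(dtype=float),
        }
    )


def read_spot_table(
    path: str | Path,
    geometry: GridGeometry,
    dialect: str = "generic_csv",
    species: str | None = None,
    coordinate_units: str = "nm",
) -> SpotTableLoad:
    """Load a spot table, validating coordinates against the image extent.

    Parameters
    ----------
    path:
        CSV file with a header row.
    geometry:
        Field-of-view geometry used for bounds checks (and for pixel→nm
        conversion when ``coordinate_units='px'``).
    dialect:
        ``'generic_csv'`` or ``'fishquant_csv'`` (see module docstring).
    species:
        Species label assigned to every row when the file carries none.
    coordinate_units:
        ``'nm'`` (default) or ``'px'``.

    Returns
    -------
    SpotTableLoad
        ``spots`` holds the validated rows (schema :data:`SPOT_COLUMNS`,
        ``spot_id`` = 0-based position in the file), ``rejected`` lists
        every dropped row with its reason.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spot table not found: {path}")
    if dialect not in ("generic_csv", "fishquant_csv"):
        raise ValueError(f"unknown spot-table dialect: {dialect!r}")
    if coordinate_units not in ("nm", "px"):
        raise ValueError(f"coordinate_units must be 'nm' or 'px', got {coordinate_units!r}")

    raw = pd.read_csv(path, comment="#")
    raw.columns = [str(c).strip() for c in raw.columns]

    if dialect == "fishquant_csv":
        lower = {c.lower(): c for c in raw.columns}
        rename = {}
        for alias, target in _FISHQUANT_ALIASES.items():
            if alias in lower:
                rename[lower[alias]] = target
        raw = raw.rename(columns=rename)

    for mandatory in ("x_nm", "y_nm"):
        if mandatory not in raw.columns:
            raise ValueError(f"{path.name}: missing mandatory column {mandatory!r} "
                             f"for dialect {dialect}")

    out = pd.DataFrame(index=raw.index)
    out["species"] = raw["species"] if "species" in raw.columns else (species or "unknown")
    out["x_nm"] = pd.to_numeric(raw["x_nm"], errors="coerce")
    out["y_nm"] = pd.to_numeric(raw["y_nm"], errors="coerce")
    out["z_nm"] = pd.to_numeric(raw["z_nm"], errors="coerce") if "z_nm" in raw.columns else np.nan
    ts_col = next((c for c in ("is_ts", "is_transcription_site") if c in raw.columns), None)
    if ts_col is not None:
        out["is_transcription_site"] = raw[ts_col].astype(bool)
    else:
        out["is_transcription_site"] = False
    nascent_col = next((c for c in ("nascent", "nascent_count") if c in raw.columns), None)
    out["nascent_count"] = pd.to_numeric(raw[nascent_col], errors="coerce") if nascent_col else np.nan

    if coordinate_units == "px":
        out["x_nm"] = out["x_nm"] * geometry.pixel_size_xy
        out["y_nm"] = out["y_nm"] * geometry.pixel_size_xy
        out["z_nm"] = out["z_nm"] * geometry.z_step

    reasons = pd.Series("", index=out.index, dtype=object)
    bad_num = out["x_nm"].isna() | out["y_nm"].isna()
    reasons[bad_num] = "non-numeric or missing coordinate"
    with np.errstate(invalid="ignore"):
        oob = ~bad_num & ~geometry.in_bounds(out["x_nm"].to_numpy(), out["y_nm"].to_numpy())
    reasons[oob] = "coordinate outside image extent"
    # nascent counts only make sense on transcription-site rows
    stray_nascent = out["nascent_count"].notna() & ~out["is_transcription_site"]
    reasons[stray_nascent & (reasons == "")] = "nascent_count on a non-transcription-site row"
    neg_nascent = out["nascent_count"].notna() & (out["nascent_count"] < 0)
    reasons[neg_nascent & (reasons == "")] = "negative nascent_count"

    bad = reasons != ""
    rejected = pd.DataFrame({"row": out.index[bad], "reason": reasons[bad].to_numpy()})
    spots = out[~bad].reset_index(drop=True)
    spots.insert(0, "spot_id", np.arange(len(spots), dtype=np.int64))
    if spots.empty:
        spots = _empty_spots()
    return SpotTableLoad(spots=spots[SPOT_COLUMNS], rejected=rejected.reset_index(drop=True))


def read_synapse_table(path: str | Path, geometry: GridGeometry) -> SpotTableLoad:
    """Load a synapse-centroid table (columns ``x_nm, y_nm``); same
    bounds-check-and-report contract as :func:`read_spot_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"synapse table not found: {path}")
    raw = pd.read_csv(path, comment="#")
    raw.columns = [str(c).strip() for c in raw.columns]
    for mandatory in ("x_nm", "y_nm"):
        if mandatory not in raw.columns:
            raise ValueError(f"{path.name}: missing mandatory column {mandatory!r}")
    out = pd.DataFrame(index=raw.index)
    out["x_nm"] = pd.to_numeric(raw["x_nm"], errors="coerce")
    out["y_nm"] = pd.to_numeric(raw["y_nm"], errors="coerce")
    reasons = pd.Series("", index=out.index, dtype=object)
    bad_num = out["x_nm"].isna() | out["y_nm"].isna()
    reasons[bad_num] = "non-numeric or missing coordinate"
    oob = ~bad_num & ~geometry.in_bounds(out["x_nm"].to_numpy(), out["y_nm"].to_numpy())
    reasons[oob] = "coordinate outside image extent"
    bad = reasons != ""
    rejected = pd.DataFrame({"row": out.index[bad], "reason": reasons[bad].to_numpy()})
    synapses = out[~bad].reset_index(drop=True)
    synapses.insert(0, "synapse_id", np.arange(len(synapses), dtype=np.int64))
    return SpotTableLoad(spots=synapses[SYNAPSE_COLUMNS], rejected=rejected.reset_index(drop=True))


# ---------------------------------------------------------------------------
# mask images
# ---------------------------------------------------------------------------

#: label legend for ``label_image`` mode
LABEL_LEGEND = {0: "background", 1: "nucleus", 2: "soma"}  # 3+ -> dendrite 1, 2, ...


def _load_image(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # RGB(A) annotation — collapse, masks are single-channel
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2D mask image, got shape {arr.shape}")
    return arr


def read_mask_image(
    paths: str | Path | list[str | Path],
    mode: str = "label_image",
) -> dict[str, np.ndarray]:
    """Read compartment masks.

    ``label_image`` mode takes one integer-labeled image (0 background,
    1 nucleus, 2 soma, 3+ dendrites) and splits it into binary masks keyed
    ``'nucleus'``, ``'soma'``, ``'dendrite_<k>'`` (dendrite k = label k+2).
    ``binary_set`` mode takes a list of files, each a binary mask, keyed by
    file stem.  All returned masks are boolean and share one shape.
    """
    if mode == "label_image":
        if isinstance(paths, (list, tuple)):
            if len(paths) != 1:
                raise ValueError("label_image mode takes exactly one image")
            paths = paths[0]
        arr = _load_image(Path(paths))
        if not np.issubdtype(arr.dtype, np.integer) and not np.issubdtype(arr.dtype, np.bool_):
            if not np.all(arr == np.round(arr)):
                raise ValueError("label_image mode requires integer labels")
            arr = arr.astype(np.int64)
        labels = sorted(int(v) for v in np.unique(arr) if v != 0)
        if not labels:
            raise ValueError("empty mask set: image contains no nonzero labels")
        masks: dict[str, np.ndarray] = {}
        for lab in labels:
            if lab == 1:
                key = "nucleus"
            elif lab == 2:
                key = "soma"
            else:
                key = f"dendrite_{lab - 2}"
            masks[key] = arr == lab
        return masks
    if mode == "binary_set":
        if not isinstance(paths, (list, tuple)):
            paths = [paths]
        masks = {}
        shape = None
        for p in paths:
            p = Path(p)
            arr = _load_image(p) > 0
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(f"mask shape mismatch: {p.name} is {arr.shape}, expected {shape}")
            masks[p.stem] = arr
        if not masks or not any(m.any() for m in masks.values()):
            raise ValueError("empty mask set")
        return masks
    raise ValueError(f"unknown mask mode: {mode!r}")


def write_mask_image(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary (or small-integer label) mask as 8-bit TIFF/PNG."""
    path = Path(path)
    arr = mask.astype(np.uint8)
    if arr.max(initial=0) == 1:
        arr = arr * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------


def write_report(results: pd.DataFrame | dict, path: str | Path, allow_empty: bool = True) -> None:
    """Write a result record set: CSV for tables, JSON for nested summaries.

    The output carries a schema-version marker (a ``#`` comment line for
    CSV, a top-level key for JSON); :func:`read_report` round-trips it.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        if results.empty and not allow_empty:
            raise ValueError(f"refusing to write empty report to {path}")
        with open(path, "w") as fh:
            fh.write(f"# schema_version={SCHEMA_VERSION}\n")
            results.to_csv(fh, index=False)
    elif isinstance(results, dict):
        if not results and not allow_empty:
            raise ValueError(f"refusing to write empty report to {path}")
        payload = {"schema_version": SCHEMA_VERSION, **results}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise TypeError(f"unsupported report type: {type(results).__name__}")


def read_report(path: str | Path) -> pd.DataFrame | dict:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        payload.pop("schema_version", None)
        return payload
    return pd.read_csv(path, comment="#")
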