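"""Compartment prints: normalized binary masks of nucleus, soma and dendrites.

Manual annotations of maximum-intensity projections are noisy: masks carry
pinholes, ragged edges, small gaps, and the hand-drawn dendrite outlines
overlap the soma and each other.  ``build_prints`` turns a raw mask set
into a consistent partition:

* every mask is hole-filled and morphologically closed (configurable
  radius, bridges small annotation gaps);
* the nucleus is clipped to the soma;
* soma pixels are removed from every dendrite (dendrites are measured from
  the soma edge outward);
* where two dendrite annotations overlap, the lower dendrite id wins;
* only the largest connected component of each print is kept.

Every normalization action is logged so imprecise annotations are repaired
loudly, not silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

NUCLEUS = "nucleus"
SOMA = "soma"
DENDRITE = "dendrite"
UNASSIGNED = "unassigned"


@dataclass
class CompartmentPrint:
    """One compartment's binary mask on the field-of-view grid."""

    label: str  # 'nucleus' | 'soma' | 'dendrite'
    mask: np.ndarray  # bool, image shape
    dendrite_id: int | None = None

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def name(self) -> str:
        if self.label == DENDRITE:
            return f"dendrite_{self.dendrite_id}"
        return self.label


@dataclass
class PrintSet:
    """Normalized prints for one field of view, plus the normalization log."""

    soma: CompartmentPrint
    nucleus: CompartmentPrint | None = None
    dendrites: list[CompartmentPrint] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.soma.mask.shape

    def dendrite(self, dendrite_id: int) -> CompartmentPrint:
        for d in self.dendrites:
            if d.dendrite_id == dendrite_id:
                return d
        raise KeyError(f"no dendrite with id {dendrite_id}")

    def dendrite_union(self) -> np.ndarray:
        """Union of all dendrite prints (the dendritic shaft domain)."""
        out = np.zeros(self.shape, dtype=bool)
        for d in self.dendrites:
            out |= d.mask
        return out

    def label_image(self) -> np.ndarray:
        """Integer label image: 0 bg, 1 nucleus, 2 soma, 3+ dendrites."""
        out = np.zeros(self.shape, dtype=np.int32)
        for d in self.dendrites:
            out[d.mask] = d.dendrite_id + 2
        out[self.soma.mask] = 2
        if self.nucleus is not None:
            out[self.nucleus.mask] = 1
        return out


def _largest_component(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Keep the largest 8-connected component; returns (mask, n_dropped_px)."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return mask, 0
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    out = labels == keep
    return out, int(mask.sum() - out.sum())


def _clean(mask: np.ndarray, closing_radius_px: int) -> np.ndarray:
    mask = mask.astype(bool)
    if closing_radius_px > 0:
        # pad so closing can bridge gaps touching the image border
        pad = closing_radius_px + 1
        padded = np.pad(mask, pad)
        padded = ndimage.binary_closing(padded, structure=disk(closing_radius_px))
        mask = padded[pad:-pad, pad:-pad]
    return ndimage.binary_fill_holes(mask)


def build_prints(raw_masks: dict[str, np.ndarray], closing_radius_px: int = 2) -> PrintSet:
    """Normalize raw annotation masks into a consistent :class:`PrintSet`.

    Parameters
    ----------
    raw_masks:
        Mapping with keys ``'soma'`` (required), ``'nucleus'`` (optional)
        and ``'dendrite_<k>'`` for each dendrite, as produced by
        :func:`neurofish.io.read_mask_image`.
    closing_radius_px:
        Radius of the morphological closing applied to every mask; 0
        disables closing.

    Raises
    ------
    ValueError
        If no soma mask is present.  A dendrite that vanishes during
        normalization is dropped and logged, never fatal.
    """
    if closing_radius_px < 0:
        raise ValueError("closing_radius_px must be >= 0")
    if "soma" not in raw_masks or not np.any(raw_masks["soma"]):
        raise ValueError("soma mask missing or empty: a soma print is required")

    log: list[str] = []
    soma = _clean(raw_masks["soma"], closing_radius_px)
    soma, dropped = _largest_component(soma)
    if dropped:
        log.append(f"soma: dropped {dropped} px outside largest component")

    nucleus_print = None
    if "nucleus" in raw_masks and np.any(raw_masks["nucleus"]):
        nucleus = _clean(raw_masks["nucleus"], closing_radius_px)
        outside = int((nucleus & ~soma).sum())
        if outside:
            log.append(f"nucleus: clipped {outside} px outside soma")
        nucleus &= soma
        nucleus, dropped = _largest_component(nucleus)
        if dropped:
            log.append(f"nucleus: dropped {dropped} px outside largest component")
        if nucleus.any():
            nucleus_print = CompartmentPrint(NUCLEUS, nucleus)
        else:
            log.append("nucleus: print vanished after normalization")

    dendrite_ids = sorted(
        int(key.split("_", 1)[1]) for key in raw_masks if key.startswith("dendrite_")
    )
    dendrites: list[CompartmentPrint] = []
    claimed = np.zeros_like(soma)  # pixels already owned by a lower dendrite id
    for did in dendrite_ids:
        mask = _clean(raw_masks[f"dendrite_{did}"], closing_radius_px)
        in_soma = int((mask & soma).sum())
        if in_soma:
            log.append(f"dendrite_{did}: removed {in_soma} px overlapping soma")
        mask &= ~soma
        overlap = int((mask & claimed).sum())
        if overlap:
            log.append(f"dendrite_{did}: yielded {overlap} px overlapping a lower dendrite id")
        mask &= ~claimed
        mask, dropped = _largest_component(mask)
        if dropped:
            log.append(f"dendrite_{did}: dropped {dropped} px outside largest component")
        if not mask.any():
            log.append(f"dendrite_{did}: print vanished after normalization, dropped")
            continue
        claimed |= mask
        dendrites.append(CompartmentPrint(DENDRITE, mask, dendrite_id=did))

    return PrintSet(soma=CompartmentPrint(SOMA, soma), nucleus=nucleus_print,
                    dendrites=dendrites, log=log)
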