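"""Nucleocytoplasmic distribution of a reporter (e.g. Mig1-GFP).

A constitutive nuclear marker (e.g. Pus1-RFP) defines a per-cell
nucleoplasmic mask (Otsu within the cell, largest component kept); the
cytoplasm is the ring obtained by dilating the nuclear mask and subtracting
it, clipped to the cell.  The per-cell readout is the mean reporter
intensity in the nucleus divided by the mean in the ring — invariant to any
multiplicative intensity change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

NO_NUCLEUS = "NO_NUCLEUS"
EMPTY_RING = "EMPTY_RING"
ZERO_CYTOPLASM = "ZERO_CYTOPLASM"


@dataclass(frozen=True)
class NucCytoImage:
    reporter: np.ndarray
    nuclear_marker: np.ndarray

    def __post_init__(self) -> None:
        rep = np.asarray(self.reporter)
        mark = np.asarray(self.nuclear_marker)
        if rep.shape != mark.shape:
            raise ValueError("reporter and marker shapes must match")
        object.__setattr__(self, "reporter", rep)
        object.__setattr__(self, "nuclear_marker", mark)


@dataclass(frozen=True)
class NCRecord:
    cell_id: int
    nuclear_mean: float | None
    cytoplasmic_mean: float | None
    nc_ratio: float | None
    flags: frozenset[str] = frozenset()

    @property
    def usable(self) -> bool:
        return not self.flags


def nuclear_mask(
    nuclear_marker: np.ndarray, cell_labels: np.ndarray
) -> tuple[np.ndarray, dict[int, str]]:
    """Per-cell nuclear label map from the marker channel.

    Within each cell region the marker is thresholded with Otsu and the
    largest connected component above threshold becomes the nucleus.  Cells
    with a constant marker (no contrast, hence no nucleus) are skipped and
    reported in the returned flag dict.
    """
    marker = np.asarray(nuclear_marker, dtype=float)
    labels_out = np.zeros(marker.shape, dtype=np.int32)
    flags: dict[int, str] = {}
    for cid in range(1, int(cell_labels.max()) + 1):
        cell = cell_labels == cid
        if not cell.any():
            continue
        values = marker[cell]
        if values.min() == values.max():
            flags[cid] = NO_NUCLEUS
            continue
        thr = threshold_otsu(values)
        above = cell & (marker > thr)
        if not above.any():
            flags[cid] = NO_NUCLEUS
            continue
        comp, n = ndi.label(above)
        sizes = ndi.sum_labels(above, comp, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        labels_out[comp == keep] = cid
    return labels_out, flags


def cytoplasm_ring(
    nuclear: np.ndarray,
    dilation_px: int = 3,
    cell_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Cytoplasmic ring: dilated nuclear mask minus the nucleus.

    The structuring element is a disc of radius ``dilation_px``; the ring is
    clipped to the cell region when one is given.  Disjoint from the nucleus
    by construction; dilation 0 yields an empty ring.
    """
    nuclear = np.asarray(nuclear, dtype=bool)
    if not nuclear.any():
        raise ValueError("nuclear mask is empty")
    if dilation_px <= 0:
        return np.zeros(nuclear.shape, dtype=bool)
    ring = ndi.binary_dilation(nuclear, structure=disk(dilation_px)) & ~nuclear
    if cell_mask is not None:
        ring &= np.asarray(cell_mask, dtype=bool)
    return ring


def nc_ratio(
    image: NucCytoImage,
    nuclear: np.ndarray,
    ring: np.ndarray,
    cell_id: int = 1,
) -> NCRecord:
    """Mean-over-mean nuclear/cytoplasmic ratio for one cell."""
    nuclear = np.asarray(nuclear, dtype=bool)
    ring = np.asarray(ring, dtype=bool)
    if not nuclear.any():
        return NCRecord(cell_id, None, None, None, frozenset({NO_NUCLEUS}))
    if not ring.any():
        return NCRecord(cell_id, None, None, None, frozenset({EMPTY_RING}))
    nuc_mean = float(image.reporter[nuclear].mean())
    cyto_mean = float(image.reporter[ring].mean())
    if cyto_mean <= 0:
        return NCRecord(
            cell_id, nuc_mean, cyto_mean, None, frozenset({ZERO_CYTOPLASM})
        )
    return NCRecord(cell_id, nuc_mean, cyto_mean, nuc_mean / cyto_mean)


def quantify_nucleocyto(
    image: NucCytoImage,
    cell_labels: np.ndarray,
    dilation_px: int = 3,
    background_offset: float = 0.0,
) -> list[NCRecord]:
    """Per-cell N/C ratios over a labelled field of cells.

    ``background_offset`` (optional) is subtracted from the reporter before
    the means; the default performs no background subtraction.
    """
    reporter = image.reporter.astype(float) - background_offset
    img = NucCytoImage(reporter=reporter, nuclear_marker=image.nuclear_marker)
    nuc_labels, flagged = nuclear_mask(image.nuclear_marker, cell_labels)
    records: list[NCRecord] = []
    for cid in range(1, int(cell_labels.max()) + 1):
        if cid in flagged:
            records.append(
                NCRecord(cid, None, None, None, frozenset({flagged[cid]}))
            )
            continue
        nuc = nuc_labels == cid
        if not nuc.any():
            records.append(NCRecord(cid, None, None, None, frozenset({NO_NUCLEUS})))
            continue
        ring = cytoplasm_ring(nuc, dilation_px, cell_mask=cell_labels == cid)
        if not ring.any():
            records.append(NCRecord(cid, None, None, None, frozenset({EMPTY_RING})))
            continue
        records.append(nc_ratio(img, nuc, ring, cid))
    return records


def population_nc_ratio(records) -> float:
    """Population mean N/C ratio over usable cells (one replicate value)."""
    usable = [r.nc_ratio for r in records if r.usable]
    if not usable:
        raise ValueError("no usable cells")
    return float(np.mean(usable))


def nc_records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "nuclear_mean": [r.nuclear_mean for r in records],
            "cytoplasmic_mean": [r.cytoplasmic_mean for r in records],
            "nc_ratio": [r.nc_ratio for r in records],
            "flags": ["|".join(sorted(r.flags)) for r in records],
        }
    )
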