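"""Probability map -> labeled nuclei -> per-nucleus measurements.

The pipeline core: binarize at 0.5, connected-component labeling,
removal of sub-200-px objects (imaging/fixation artifacts), then
mean/total intensity per nucleus in both channels.  Intensities are
reported in native camera units with no background subtraction; nuclei
touching the field border are retained.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ChannelImage, NucleusLabelMap, NucleusRecord

DEFAULT_MIN_AREA_PX = 200

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    8: np.ones((3, 3), bool),
}


def binarize(pmap: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties at the threshold count as nucleus."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie strictly in (0, 1), got {threshold}")
    pmap = np.asarray(pmap)
    if np.any((pmap < 0) | (pmap > 1)):
        raise ValueError("probability map contains values outside [0, 1]")
    return pmap >= threshold


def label_components(mask: np.ndarray, connectivity: int = 8) -> NucleusLabelMap:
    """Group foreground pixels into components under 4- or 8-adjacency."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask).astype(bool)
    labels, _ = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    return NucleusLabelMap(labels=labels.astype(np.int32), connectivity=connectivity)


def filter_small(labels: NucleusLabelMap,
                 min_area_px: int = DEFAULT_MIN_AREA_PX) -> NucleusLabelMap:
    """Delete components with area strictly below ``min_area_px``.

    Survivors are relabeled 1..K preserving the original label order;
    the operation is idempotent.
    """
    if min_area_px < 0:
        raise ValueError(f"min_area_px must be non-negative, got {min_area_px}")
    arr = labels.labels
    n = int(arr.max(initial=0))
    if n == 0:
        return NucleusLabelMap(labels=arr.copy(), connectivity=labels.connectivity)
    areas = np.bincount(arr.ravel(), minlength=n + 1)
    keep = areas >= min_area_px
    keep[0] = False
    remap = np.zeros(n + 1, dtype=arr.dtype)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    return NucleusLabelMap(labels=remap[arr], connectivity=labels.connectivity)


def area_to_um2(area_px: float, pixel_pitch: float) -> float:
    """Convert a pixel area to um^2 given the pixel pitch (um per side)."""
    if pixel_pitch <= 0:
        raise ValueError(f"pixel_pitch must be positive, got {pixel_pitch}")
    return float(area_px) * pixel_pitch ** 2


def measure_nuclei(labels: NucleusLabelMap, dapi: ChannelImage,
                   gh2ax: ChannelImage) -> List[NucleusRecord]:
    """One record per label: area, centroid, mean/total intensity per channel.

    Means are taken over exactly the labeled pixels (no background
    correction); the label mask from the DAPI channel is transferred
    unchanged onto the gH2AX channel.
    """
    if labels.shape != dapi.shape or labels.shape != gh2ax.shape:
        raise ValueError(
            f"shape mismatch: labels {labels.shape}, dapi {dapi.shape}, "
            f"gh2ax {gh2ax.shape}"
        )
    arr = labels.labels
    n = int(arr.max(initial=0))
    if n == 0:
        return []
    index = np.arange(1, n + 1)
    areas = np.bincount(arr.ravel(), minlength=n + 1)[1:]
    dapi_data = dapi.data.astype(np.float64)
    gh_data = gh2ax.data.astype(np.float64)
    sum_dapi = ndimage.sum_labels(dapi_data, arr, index)
    sum_gh = ndimage.sum_labels(gh_data, arr, index)
    centroids = ndimage.center_of_mass(np.ones_like(arr, dtype=np.float64), arr, index)
    pitch = dapi.pixel_pitch
    return [
        NucleusRecord(
            label=int(lab),
            area_px=int(a),
            area_um2=area_to_um2(int(a), pitch),
            centroid=(float(cr), float(cc)),
            mean_dapi=float(sd / a),
            total_dapi=float(sd),
            mean_gh2ax=float(sg / a),
            total_gh2ax=float(sg),
            plate=dapi.plate,
            well=dapi.well,
            field=dapi.field,
        )
        for lab, a, sd, sg, (cr, cc) in zip(index, areas, sum_dapi, sum_gh, centroids)
    ]


NUCLEUS_CSV_COLUMNS = [
    "plate", "well", "field", "label", "area_px", "area_um2",
    "centroid_row", "centroid_col", "mean_dapi", "total_dapi",
    "mean_gh2ax", "total_gh2ax",
]


def records_to_frame(records: List[NucleusRecord]) -> pd.DataFrame:
    """Tidy per-nucleus table in the CSV export column order."""
    rows = [
        {
            "plate": r.plate, "well": r.well, "field": r.field, "label": r.label,
            "area_px": r.area_px, "area_um2": r.area_um2,
            "centroid_row": r.centroid[0], "centroid_col": r.centroid[1],
            "mean_dapi": r.mean_dapi, "total_dapi": r.total_dapi,
            "mean_gh2ax": r.mean_gh2ax, "total_gh2ax": r.total_gh2ax,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=NUCLEUS_CSV_COLUMNS)
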