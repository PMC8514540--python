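"""Shared in-memory containers for the imaging pipeline.

Intensities are kept in native camera units (16-bit counts); no
normalization is applied anywhere upstream of the dose-response stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: side length of one pixel, in micrometres, matching the equivalence
#: 200 px == 20.8 um^2 (sqrt(20.8 / 200) = 0.32249...)
DEFAULT_PIXEL_PITCH_UM = 0.3225


@dataclass
class ChannelImage:
    """One 2-D intensity grid from a single fluorescence channel.

    Parameters
    ----------
    data : ndarray
        2-D array of pixel intensities (uint16 or float).
    channel : str
        ``"dapi"`` (nuclear stain, segmentation channel) or ``"gh2ax"``
        (DNA damage immunostain).
    pixel_pitch : float
        Micrometres per pixel side.
    plate, well, field : str, optional
        Acquisition provenance.
    """

    data: np.ndarray
    channel: str
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM
    plate: Optional[str] = None
    well: Optional[str] = None
    field: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"ChannelImage data must be 2-D, got shape {self.data.shape}")
        if self.channel not in ("dapi", "gh2ax"):
            raise ValueError(f"channel must be 'dapi' or 'gh2ax', got {self.channel!r}")
        if self.pixel_pitch <= 0:
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class NucleusLabelMap:
    """Integer-labeled segmentation; 0 is background, labels run 1..K.

    ``connectivity`` records the pixel adjacency (4 or 8) used when the
    components were formed.
    """

    labels: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> tuple:
        return self.labels.shape


@dataclass
class NucleusRecord:
    """Per-nucleus measurements in both imaging channels."""

    label: int
    area_px: int
    area_um2: float
    centroid: tuple  # (row, col) in pixels
    mean_dapi: float
    total_dapi: float
    mean_gh2ax: float
    total_gh2ax: float
    plate: Optional[str] = None
    well: Optional[str] = None
    field: Optional[str] = None
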