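"""Seeded synthetic two-channel microscopy fields with exact ground truth.

Each scene emulates a fixed-cell fluorescence field: ellipse-shaped
nuclei rendered into a DAPI channel over a dim background, a gH2AX
channel that is stained only inside nuclei (basal level everywhere, a
multiplicative gain for the "damaged" subpopulation), optical blur via
a Gaussian PSF, then mixed Poisson-Gaussian camera noise and 16-bit
quantization.  The true label map and per-nucleus generative
parameters ride along, so segmentation and measurement can be scored
against exact truth without any downloaded data.

Dose plates follow a four-parameter logistic: the expected nuclei
count per field falls with the reference-compound concentration, and
wells at or above an activation threshold switch most surviving nuclei
into the gH2AX-positive state.
"""

from __future__ import annotations

import csv
import pathlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import ChannelImage, NucleusLabelMap, DEFAULT_PIXEL_PITCH_UM
from .doseresponse import four_param_logistic
from .pipeline import PlateLayout

_MAX_PLACEMENT_ATTEMPTS = 200


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters of one synthetic field.

    Intensity units are 16-bit camera counts.  Defaults draw nuclei of
    3.5–6.5 um semi-axes (areas well above the 200-px artifact filter at
    the default pitch) at a density typical of a healthy well.
    """

    field_shape: Tuple[int, int] = (256, 256)
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM
    n_nuclei: int = 13
    nucleus_axes_range: Tuple[float, float] = (3.5, 6.5)  # um, semi-axes
    dapi_intensity_range: Tuple[float, float] = (8000.0, 16000.0)
    gh2ax_positive_fraction: float = 0.2
    gh2ax_positive_gain: float = 4.0
    psf_sigma: float = 1.0  # px; 0 disables blur
    noise_gaussian_sd: float = 50.0  # counts; 0 disables
    noise_poisson_scale: float = 0.05  # photons per count; 0 disables
    overlap_allowed: bool = False
    seed: int = 0
    # background / basal levels (counts) and placement margin
    dapi_background: float = 300.0
    gh2ax_background: float = 100.0
    gh2ax_basal: float = 2000.0
    min_separation_px: float = 2.0

    def __post_init__(self) -> None:
        rows, cols = self.field_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"field_shape must be positive, got {self.field_shape}")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        for name in ("nucleus_axes_range", "dapi_intensity_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < min <= max, got ({lo}, {hi})")
        if not 0.0 <= self.gh2ax_positive_fraction <= 1.0:
            raise ValueError("gh2ax_positive_fraction must lie in [0, 1]")
        if self.gh2ax_positive_gain <= 1.0:
            raise ValueError("gh2ax_positive_gain must exceed 1")
        max_axis_px = self.nucleus_axes_range[1] / self.pixel_pitch
        if self.n_nuclei > 0 and 2 * max_axis_px >= min(rows, cols):
            raise ValueError(
                "nucleus_axes_range: largest nucleus "
                f"({2 * max_axis_px:.0f} px diameter) does not fit the "
                f"{rows}x{cols} field"
            )


@dataclass
class NucleusTruth:
    label: int
    center: Tuple[float, float]  # (row, col) px
    axes: Tuple[float, float]  # (a, b) semi-axes, px
    orientation: float  # radians
    is_gh2ax_positive: bool
    true_mean_gh2ax: float  # pre-blur, pre-noise nuclear level
    dapi_level: float


@dataclass
class GroundTruthScene:
    dapi: ChannelImage
    gh2ax: ChannelImage
    true_labels: NucleusLabelMap
    nuclei_truth: List[NucleusTruth]
    params: SceneParams


def _ellipse_mask(shape, center, axes, theta) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _apply_camera(signal: np.ndarray, p: SceneParams, rng: np.random.Generator
                  ) -> np.ndarray:
    """PSF blur, then Poisson shot noise and Gaussian read noise, uint16."""
    img = signal.astype(np.float64)
    if p.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, p.psf_sigma, mode="reflect")
    if p.noise_poisson_scale > 0:
        img = rng.poisson(img * p.noise_poisson_scale) / p.noise_poisson_scale
    if p.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, p.noise_gaussian_sd, img.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def generate_scene(params: SceneParams) -> GroundTruthScene:
    """Render one two-channel field with exact ground truth.

    Deterministic for fixed params (seed included).  Ellipses are laid
    down before blur and noise, so ``true_labels`` is the exact
    pre-degradation geometry.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    shape = tuple(p.field_shape)
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    truth: List[NucleusTruth] = []

    lo_px = p.nucleus_axes_range[0] / p.pixel_pitch
    hi_px = p.nucleus_axes_range[1] / p.pixel_pitch

    for lab in range(1, p.n_nuclei + 1):
        placed = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            axes = rng.uniform(lo_px, hi_px, size=2)
            theta = rng.uniform(0.0, np.pi)
            margin = axes.max()
            center = (
                rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin),
            )
            mask = _ellipse_mask(shape, center, axes, theta)
            if not p.overlap_allowed:
                spaced = _ellipse_mask(
                    shape, center, axes + p.min_separation_px, theta)
                if (spaced & occupied).any():
                    continue
            labels[mask] = lab
            occupied |= _ellipse_mask(shape, center, axes + p.min_separation_px, theta)
            truth.append(NucleusTruth(
                label=lab, center=center, axes=tuple(axes), orientation=theta,
                is_gh2ax_positive=False, true_mean_gh2ax=0.0, dapi_level=0.0,
            ))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place nucleus {lab}/{p.n_nuclei} without overlap "
                f"after {_MAX_PLACEMENT_ATTEMPTS} attempts; lower n_nuclei or "
                "allow overlap"
            )

    dapi_signal = np.full(shape, p.dapi_background, dtype=np.float64)
    gh_signal = np.full(shape, p.gh2ax_background, dtype=np.float64)
    for t in truth:
        nucleus = labels == t.label
        level = float(np.rint(rng.uniform(*p.dapi_intensity_range)))
        positive = bool(rng.random() < p.gh2ax_positive_fraction)
        gh_level = p.gh2ax_basal * (p.gh2ax_positive_gain if positive else 1.0)
        dapi_signal[nucleus] = level
        gh_signal[nucleus] = gh_level
        t.dapi_level = level
        t.is_gh2ax_positive = positive
        t.true_mean_gh2ax = gh_level

    dapi = ChannelImage(_apply_camera(dapi_signal, p, rng), "dapi", p.pixel_pitch)
    gh2ax = ChannelImage(_apply_camera(gh_signal, p, rng), "gh2ax", p.pixel_pitch)
    return GroundTruthScene(
        dapi=dapi, gh2ax=gh2ax,
        true_labels=NucleusLabelMap(labels=labels, connectivity=8),
        nuclei_truth=truth, params=p,
    )


@dataclass(frozen=True)
class DoseResponseTruth:
    """Generating 4PL for the expected per-field nuclei count.

    ``top_count``/``bottom_count`` are expected nuclei per field at the
    zero-dose / saturating asymptotes; ``gh2ax_threshold_uM`` is the
    concentration at and above which the damaged (gH2AX-positive)
    fraction jumps to ``damaged_positive_fraction``.
    """

    pic50: float = 5.0
    hill: float = 1.5
    top_count: float = 40.0
    bottom_count: float = 0.0
    gh2ax_threshold_uM: float = float("inf")
    damaged_positive_fraction: float = 0.9

    def expected_count(self, concentration_uM: float) -> float:
        if concentration_uM < 0:
            raise ValueError("concentration must be non-negative")
        if concentration_uM == 0:
            return self.top_count
        return float(four_param_logistic(
            concentration_uM, self.bottom_count, self.top_count,
            self.pic50, self.hill,
        ))


def generate_dose_plate(layout: PlateLayout,
                        dr_truth: Union[DoseResponseTruth,
                                        Dict[str, DoseResponseTruth]],
                        scene_params: SceneParams
                        ) -> Dict[str, List[GroundTruthScene]]:
    """Simulate every field of a dose plate.

    Per-field nuclei counts are Poisson draws around the generating
    4PL evaluated at each well's concentration (controls sit at the
    zero-dose asymptote); field seeds derive deterministically from
    ``scene_params.seed`` and the well/field position.  ``dr_truth``
    may be a single truth, or a dict keyed by condition name when
    different conditions on the plate follow different curves (the
    control asymptote is then taken from the first entry).
    """
    rng = np.random.default_rng(scene_params.seed)
    truths = ({"__single__": dr_truth}
              if isinstance(dr_truth, DoseResponseTruth) else dict(dr_truth))
    single = "__single__" in truths
    default_truth = next(iter(truths.values()))
    out: Dict[str, List[GroundTruthScene]] = {}
    for well in sorted(layout.wells):
        cond = layout.wells[well]
        if cond.is_control:
            truth = default_truth
        elif single:
            truth = truths["__single__"]
        elif cond.condition in truths:
            truth = truths[cond.condition]
        else:
            raise ValueError(
                f"well {well!r} has condition {cond.condition!r} with no "
                "dose-response truth coverage"
            )
        expected = truth.expected_count(cond.concentration_uM)
        positive_fraction = (
            truth.damaged_positive_fraction
            if not cond.is_control
            and cond.concentration_uM >= truth.gh2ax_threshold_uM
            else scene_params.gh2ax_positive_fraction
        )
        scenes = []
        for f in range(layout.fields_per_well):
            n = int(rng.poisson(expected))
            field_seed = int(rng.integers(0, 2 ** 31 - 1))
            sp = replace(
                scene_params, n_nuclei=n, seed=field_seed,
                gh2ax_positive_fraction=positive_fraction,
                pixel_pitch=layout.pixel_pitch,
            )
            scene = generate_scene(sp)
            scene.dapi.plate = scene.gh2ax.plate = layout.plate_id
            scene.dapi.well = scene.gh2ax.well = well
            scene.dapi.field = scene.gh2ax.field = str(f)
            scenes.append(scene)
        out[well] = scenes
    return out


def write_scene(scene: GroundTruthScene, root, plate: str = "plate01",
                well: str = "A01", field_name: str = "0") -> pathlib.Path:
    """Write a scene to disk: per-channel 16-bit TIFFs, label TIFF, truth CSV.

    Layout: ``<root>/<plate>/<well>/<field>_<channel>.tif``.
    """
    import tifffile

    d = pathlib.Path(root) / plate / well
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / f"{field_name}_dapi.tif", scene.dapi.data.astype(np.uint16))
    tifffile.imwrite(d / f"{field_name}_gh2ax.tif", scene.gh2ax.data.astype(np.uint16))
    tifffile.imwrite(d / f"{field_name}_labels.tif",
                     scene.true_labels.labels.astype(np.uint16))
    with open(d / f"{field_name}_truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "center_row", "center_col", "is_positive",
                    "true_mean_gh2ax"])
        for t in scene.nuclei_truth:
            w.writerow([t.label, t.center[0], t.center[1],
                        int(t.is_gh2ax_positive), t.true_mean_gh2ax])
    return d
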