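"""End-to-end plate orchestration: images in, fits out.

A plate is a grid of wells, each imaged as several fields (25 in the
source assay design).  Every field runs the fixed stage chain

    compute_features -> predict_proba -> binarize(0.5)
    -> label_components -> filter_small(200 px) -> measure_nuclei

then wells are summarized (nuclei counted over fields, counts
normalized to the same-plate PBS-control mean), summaries are pooled
across independent experiments, and 4PL dose-response curves are
fitted to the normalized counts.  Normalization happens within each
experiment before pooling, so a global intensity-gain change on one
plate cannot bias the pooled percentages.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierModel, predict_proba
from .core import ChannelImage, NucleusRecord, DEFAULT_PIXEL_PITCH_UM
from .doseresponse import (
    DoseResponseCurve, DoseResponseFit, TreatmentCondition, fit_4pl,
    normalize_to_control, pIC50_to_IC50,
)
from .features import FeatureConfig, compute_features
from .segment import (
    binarize, filter_small, label_components, measure_nuclei, records_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WellCondition:
    """What one well received: a condition at one dose, or control."""

    condition: str = "control"
    concentration_uM: float = 0.0  # reference-component concentration
    is_control: bool = False
    components: Tuple[Tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.concentration_uM < 0:
            raise ValueError("concentration must be non-negative")


CONTROL = WellCondition(condition="control", concentration_uM=0.0, is_control=True)


@dataclass
class PlateLayout:
    """Well -> treatment map for one plate.

    At least one control well is required: it anchors the within-plate
    normalization of nuclei counts.
    """

    plate_id: str
    wells: Dict[str, WellCondition]
    fields_per_well: int = 25
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        if not any(w.is_control for w in self.wells.values()):
            raise ValueError(f"plate {self.plate_id!r} has no control well")
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")

    def control_wells(self) -> List[str]:
        return [w for w, c in self.wells.items() if c.is_control]

    @classmethod
    def from_condition(cls, plate_id: str, cond: TreatmentCondition,
                       replicate_wells: int = 2, control_wells: int = 2,
                       fields_per_well: int = 25,
                       pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM) -> "PlateLayout":
        """Lay a single dilution series plus controls onto a plate."""
        from .doseresponse import make_dilution_series

        series = make_dilution_series(cond)
        ref = series[cond.components[0][0]]
        wells: Dict[str, WellCondition] = {}
        for i, conc in enumerate(ref):
            for r in range(replicate_wells):
                row = chr(ord("A") + r)
                wells[f"{row}{i + 1:02d}"] = WellCondition(
                    condition=cond.name, concentration_uM=float(conc),
                    components=cond.components,
                )
        for r in range(control_wells):
            row = chr(ord("A") + r)
            wells[f"{row}{len(ref) + 1:02d}"] = CONTROL
        return cls(plate_id=plate_id, wells=wells,
                   fields_per_well=fields_per_well, pixel_pitch=pixel_pitch)

    @classmethod
    def from_conditions(cls, plate_id: str, conds: Sequence[TreatmentCondition],
                        replicate_wells: int = 1, control_wells: int = 2,
                        fields_per_well: int = 25,
                        pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM) -> "PlateLayout":
        """Several dilution series side by side on one plate, plus controls."""
        from .doseresponse import make_dilution_series

        wells: Dict[str, WellCondition] = {}
        row_idx = 0
        for cond in conds:
            series = make_dilution_series(cond)
            ref = series[cond.components[0][0]]
            for r in range(replicate_wells):
                row = chr(ord("A") + row_idx)
                for i, conc in enumerate(ref):
                    wells[f"{row}{i + 1:02d}"] = WellCondition(
                        condition=cond.name, concentration_uM=float(conc),
                        components=cond.components,
                    )
                row_idx += 1
        row = chr(ord("A") + row_idx)
        for r in range(control_wells):
            wells[f"{row}{r + 1:02d}"] = CONTROL
        return cls(plate_id=plate_id, wells=wells,
                   fields_per_well=fields_per_well, pixel_pitch=pixel_pitch)


@dataclass
class WellSummary:
    well: str
    condition: str
    concentration_uM: float
    is_control: bool
    n_nuclei: int
    n_nuclei_pct_control: float
    mean_of_mean_gh2ax: float
    n_fields_used: int
    low_count: bool


@dataclass
class PipelineConfig:
    """Single versioned bundle of every tunable in the stage chain.

    Its hash is stamped into every output row for provenance; a trained
    model carrying a different feature hash refuses to run.
    """

    feature: FeatureConfig = field(default_factory=FeatureConfig)
    threshold: float = 0.5
    min_area_px: int = 200
    connectivity: int = 8
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM
    min_nuclei_per_well: int = 50
    seed: int = 0

    def hash(self) -> str:
        key = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(key.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature"]["sigmas"] = list(self.feature.sigmas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        feat = d.pop("feature", {})
        return cls(feature=FeatureConfig(**feat), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_field(dapi: ChannelImage, gh2ax: ChannelImage, model: ClassifierModel,
              config: Optional[PipelineConfig] = None) -> List[NucleusRecord]:
    """Run the fixed stage chain on one field; returns per-nucleus records."""
    config = config or PipelineConfig()
    if dapi.shape != gh2ax.shape:
        raise ValueError(f"channel shapes differ: {dapi.shape} vs {gh2ax.shape}")
    if model.config_hash and model.config_hash != config.feature.hash():
        raise ValueError(
            "model was trained under a different feature config "
            f"(hash {model.config_hash} != {config.feature.hash()})"
        )
    stack = compute_features(dapi, config.feature)
    pmap = predict_proba(model, stack)
    mask = binarize(pmap, config.threshold)
    labels = label_components(mask, config.connectivity)
    filtered = filter_small(labels, config.min_area_px)
    if filtered.n_labels > labels.n_labels:
        raise AssertionError("size filter increased the component count")
    records = measure_nuclei(filtered, dapi, gh2ax)
    logger.info(
        "field %s/%s/%s: fg_px=%d components=%d after_filter=%d",
        dapi.plate, dapi.well, dapi.field,
        int(mask.sum()), labels.n_labels, filtered.n_labels,
    )
    return records


def summarize_well(field_records: Sequence[Sequence[NucleusRecord]], well: str,
                   condition: WellCondition,
                   control_mean_count: Optional[float] = None,
                   min_nuclei: int = 50) -> WellSummary:
    """Aggregate one well: count over fields, % of control, mean gH2AX."""
    counts = [len(recs) for recs in field_records]
    n = int(sum(counts))
    if control_mean_count is not None:
        if not control_mean_count > 0:
            raise ValueError("control mean count must be positive")
        pct = float(normalize_to_control([n], [control_mean_count])[0])
    else:
        pct = float("nan")
    means = [r.mean_gh2ax for recs in field_records for r in recs]
    mean_gh = float(np.mean(means)) if means else float("nan")
    return WellSummary(
        well=well, condition=condition.condition,
        concentration_uM=condition.concentration_uM,
        is_control=condition.is_control, n_nuclei=n,
        n_nuclei_pct_control=pct, mean_of_mean_gh2ax=mean_gh,
        n_fields_used=len(counts), low_count=n < min_nuclei,
    )


PlateImages = Dict[str, List[Tuple[ChannelImage, ChannelImage]]]


def process_plate(layout: PlateLayout, images: PlateImages,
                  model: ClassifierModel, config: PipelineConfig
                  ) -> Tuple[List[NucleusRecord], List[WellSummary]]:
    """Segment every field of one plate and summarize its wells.

    A field that fails is quarantined (logged, skipped); the run
    continues with the remaining fields.
    """
    per_well: Dict[str, List[List[NucleusRecord]]] = {}
    all_records: List[NucleusRecord] = []
    for well, fields in images.items():
        if well not in layout.wells:
            raise KeyError(f"well {well!r} not present in layout {layout.plate_id!r}")
        per_field: List[List[NucleusRecord]] = []
        for i, (dapi, gh) in enumerate(fields):
            try:
                recs = run_field(dapi, gh, model, config)
            except ValueError as exc:
                logger.error("field %s/%s/%d failed, skipping: %s",
                             layout.plate_id, well, i, exc)
                continue
            per_field.append(recs)
            all_records.extend(recs)
        per_well[well] = per_field

    control_counts = [
        sum(len(fr) for fr in per_well[w])
        for w in layout.control_wells() if w in per_well
    ]
    control_mean = float(np.mean(control_counts)) if control_counts else None
    summaries = [
        summarize_well(per_well[w], w, layout.wells[w], control_mean,
                       config.min_nuclei_per_well)
        for w in per_well
    ]
    return all_records, summaries


def run_experiment(plates: Sequence[Tuple[PlateLayout, PlateImages]],
                   model: ClassifierModel,
                   config: Optional[PipelineConfig] = None,
                   outdir=None) -> Dict[str, object]:
    """Full multi-plate run: per-nucleus / per-well tables and 4PL fits.

    Each plate is normalized within itself before pooling across
    plates (independent experiments).  Wells below the nucleus-count
    floor keep their counts but are excluded from pooled gH2AX means.
    Returns a dict with ``nuclei``, ``wells`` and ``fits`` entries; with
    ``outdir`` set the three tables are also written as CSV, every row
    stamped with the config hash.
    """
    config = config or PipelineConfig()
    pitches = {layout.pixel_pitch for layout, _ in plates}
    if len(pitches) > 1:
        raise ValueError(f"mixed pixel pitches across pooled plates: {sorted(pitches)}")

    nuc_frames = []
    well_rows = []
    for layout, images in plates:
        records, summaries = process_plate(layout, images, model, config)
        df = records_to_frame(records)
        df.insert(0, "plate", df.pop("plate").fillna(layout.plate_id))
        nuc_frames.append(df)
        for s in summaries:
            well_rows.append({"plate": layout.plate_id, **asdict(s)})

    nuclei = pd.concat(nuc_frames, ignore_index=True) if nuc_frames else records_to_frame([])
    wells = pd.DataFrame(well_rows).sort_values(["plate", "well"]).reset_index(drop=True)

    fits: Dict[str, DoseResponseFit] = {}
    fit_rows = []
    treated = wells[~wells["is_control"] & (wells["concentration_uM"] > 0)]
    for condition, grp in treated.groupby("condition", sort=True):
        curve = DoseResponseCurve(
            concentrations=grp["concentration_uM"].to_numpy(),
            responses=grp["n_nuclei_pct_control"].to_numpy(),
            condition=condition,
        )
        if np.unique(curve.concentrations).size < 4:
            logger.info("condition %s: too few concentrations for a fit", condition)
            continue
        fit = fit_4pl(curve)
        fits[condition] = fit
        fit_rows.append({
            "condition": condition,
            "pIC50": fit.pic50,
            "pIC50_lo": fit.pic50_ci95[0], "pIC50_hi": fit.pic50_ci95[1],
            "IC50_uM": pIC50_to_IC50(fit.pic50) if fit.converged else float("nan"),
            "bottom_pct": fit.bottom,
            "bottom_lo": fit.bottom_ci95[0], "bottom_hi": fit.bottom_ci95[1],
            "hill": fit.hill, "converged": fit.converged, "status": fit.status,
            "n_obs": fit.n_obs,
        })
    fit_table = pd.DataFrame(fit_rows)

    chash = config.hash()
    for df in (nuclei, wells, fit_table):
        if len(df.columns):
            df["config_hash"] = chash

    if outdir is not None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        nuclei.to_csv(out / "nuclei.csv", index=False)
        wells.to_csv(out / "wells.csv", index=False)
        fit_table.to_csv(out / "fits.csv", index=False)

    return {"nuclei": nuclei, "wells": wells, "fits": fits, "fit_table": fit_table}
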