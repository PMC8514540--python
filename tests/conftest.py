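"""Shared fixtures: the heavy synthetic benchmarks run once per session."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import hcscreen as h

# make sibling oracle helpers importable regardless of invocation dir
import sys
import pathlib

sys.path.insert(0, str(pathlib.Path(__file__).parent))


@pytest.fixture(scope="session")
def benchmark_result():
    """Default seeded segmentation benchmark (12 fields, train 4 / test 8)."""
    return h.run_segmentation_benchmark()


DOSE_SCENE_PARAMS = h.SceneParams(
    field_shape=(288, 288), nucleus_axes_range=(2.7, 3.8), n_nuclei=40,
)
DOSE_TRUTH = h.DoseResponseTruth()  # pIC50 5.0, hill 1.5, top 40 nuclei/field


@pytest.fixture(scope="session")
def dose_experiment():
    """Three simulated replicate plates of one compound plus the fitted result.

    Mirrors the pooling design of the assay: dilution series in duplicate
    wells, several fields per well, three independent experiments
    normalized to their own PBS controls before pooling.
    """
    cond = h.TreatmentCondition(components=(("drugA", 1.0),),
                                top_concentration=100.0, n_points=7)
    layouts = [
        h.PlateLayout.from_condition(
            f"exp{i}", cond, replicate_wells=2, control_wells=2,
            fields_per_well=4, pixel_pitch=DOSE_SCENE_PARAMS.pixel_pitch)
        for i in range(3)
    ]
    plates = [
        h.generate_dose_plate(layout, DOSE_TRUTH,
                              replace(DOSE_SCENE_PARAMS, seed=100 + i))
        for i, layout in enumerate(layouts)
    ]

    train_scenes = [h.generate_scene(replace(DOSE_SCENE_PARAMS, seed=900 + i))
                    for i in range(2)]
    config = h.PipelineConfig(pixel_pitch=DOSE_SCENE_PARAMS.pixel_pitch)
    stacks = [h.compute_features(s.dapi, config.feature) for s in train_scenes]
    anns = [h.AnnotationMask.from_ground_truth(s.true_labels, rng=i,
                                               max_per_class=4000)
            for i, s in enumerate(train_scenes)]
    model = h.train(stacks, anns, n_trees=100, seed=0)

    experiment = [
        (layout, {w: [(s.dapi, s.gh2ax) for s in scenes]
                  for w, scenes in plate.items()})
        for layout, plate in zip(layouts, plates)
    ]
    result = h.run_experiment(experiment, model, config)
    return {
        "condition": cond, "layouts": layouts, "plates": plates,
        "model": model, "config": config, "result": result,
        "truth": DOSE_TRUTH,
    }


@pytest.fixture(scope="session")
def small_trained_model():
    """Classifier trained on two small synthetic fields; quick to build."""
    params = h.SceneParams(field_shape=(128, 128), n_nuclei=5)
    scenes = [h.generate_scene(replace(params, seed=300 + i)) for i in range(3)]
    stacks = [h.compute_features(s.dapi) for s in scenes]
    anns = [h.AnnotationMask.from_ground_truth(s.true_labels, rng=i,
                                               max_per_class=2500)
            for i, s in enumerate(scenes[:2])]
    model = h.train(stacks[:2], anns, n_trees=50, seed=0)
    return {"params": params, "scenes": scenes, "stacks": stacks, "model": model}
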