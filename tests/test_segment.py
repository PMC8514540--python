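"""Segmentation core: thresholding, labeling vs flood-fill oracle,
size filtering, unit conversion, per-nucleus measurement."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hcscreen as h
from hcscreen.core import NucleusLabelMap
from oracles import flood_fill_label, labelings_equivalent, surviving_component_count


class TestBinarize:
    def test_all_zero_map_gives_empty_mask(self):
        assert not h.binarize(np.zeros((5, 5))).any()

    def test_exact_threshold_counts_as_foreground(self):
        pmap = np.array([[0.49, 0.5, 0.51]])
        np.testing.assert_array_equal(h.binarize(pmap, 0.5),
                                      [[False, True, True]])

    def test_indicator_map_reproduced_exactly(self):
        rng = np.random.default_rng(0)
        truth = rng.random((20, 20)) > 0.6
        np.testing.assert_array_equal(h.binarize(truth.astype(float)), truth)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_range_threshold_rejected(self, bad):
        with pytest.raises(ValueError):
            h.binarize(np.zeros((2, 2)), bad)


class TestLabelComponents:
    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.array([[1, 0], [0, 1]], bool)
        assert h.label_components(mask, 8).n_labels == 1
        assert h.label_components(mask, 4).n_labels == 2

    def test_checkerboard_under_4_connectivity(self):
        mask = np.indices((4, 4)).sum(axis=0) % 2 == 0
        assert h.label_components(mask, 4).n_labels == 8

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_masks(self, connectivity):
        rng = np.random.default_rng(17)
        for _ in range(100):
            mask = rng.random((64, 64)) < rng.uniform(0.2, 0.7)
            ours = h.label_components(mask, connectivity).labels
            oracle = flood_fill_label(mask, connectivity)
            assert labelings_equivalent(ours, oracle)

    def test_empty_mask_yields_zero_labels(self):
        assert h.label_components(np.zeros((6, 6), bool)).n_labels == 0


class TestFilterSmall:
    def _labelmap_with_areas(self, areas):
        width = max(areas)
        arr = np.zeros((2 * len(areas), width), dtype=np.int32)
        for i, a in enumerate(areas):
            arr[2 * i, :a] = i + 1
        return NucleusLabelMap(labels=arr, connectivity=8)

    def test_strict_inequality_at_the_200px_boundary(self):
        lm = self._labelmap_with_areas([150, 199, 200, 250])
        out = h.filter_small(lm, 200)
        surviving = np.bincount(out.labels.ravel())[1:]
        assert sorted(surviving) == [200, 250]

    def test_zero_min_area_is_identity(self):
        lm = self._labelmap_with_areas([3, 7, 11])
        np.testing.assert_array_equal(h.filter_small(lm, 0).labels, lm.labels)

    def test_negative_min_area_rejected(self):
        with pytest.raises(ValueError):
            h.filter_small(self._labelmap_with_areas([5]), -1)

    def test_relabeling_consecutive_and_order_preserving(self):
        lm = self._labelmap_with_areas([10, 2, 10, 1, 10])
        out = h.filter_small(lm, 5)
        # original labels 1, 3, 5 survive and become 1, 2, 3 in order
        assert np.array_equal(np.unique(out.labels), [0, 1, 2, 3])
        assert out.labels[0, 0] == 1 and out.labels[4, 0] == 2 and out.labels[8, 0] == 3

    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 40))
    @settings(max_examples=40, deadline=None)
    def test_survivor_count_matches_enumeration_and_idempotence(self, seed, min_area):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48)) < 0.45
        lm = h.label_components(mask, 8)
        out = h.filter_small(lm, min_area)
        assert out.n_labels == surviving_component_count(lm.labels, min_area)
        np.testing.assert_array_equal(h.filter_small(out, min_area).labels,
                                      out.labels)
        # monotone: a stricter filter never keeps more objects
        assert h.filter_small(lm, min_area + 5).n_labels <= out.n_labels


class TestAreaConversion:
    def test_paper_equivalence_200px(self):
        assert h.area_to_um2(200, 0.3225) == pytest.approx(20.8, abs=0.05)

    @pytest.mark.parametrize("px,pitch,expected", [(0, 0.3225, 0.0), (1, 1.0, 1.0)])
    def test_trivial_conversions(self, px, pitch, expected):
        assert h.area_to_um2(px, pitch) == expected

    def test_nonpositive_pitch_rejected(self):
        with pytest.raises(ValueError):
            h.area_to_um2(10, 0.0)


class TestMeasureNuclei:
    def _channels(self, dapi, gh2ax, pitch=0.3225):
        return (h.ChannelImage(dapi, "dapi", pitch),
                h.ChannelImage(gh2ax, "gh2ax", pitch))

    def test_uniform_region_means_and_totals(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        labels[0, :5] = 1
        labels[2, :5] = 1  # 10-px nucleus
        dapi, gh = self._channels(np.full((5, 5), 3.0), np.full((5, 5), 7.0))
        (rec,) = h.measure_nuclei(NucleusLabelMap(labels), dapi, gh)
        assert rec.area_px == 10
        assert rec.mean_gh2ax == pytest.approx(7.0)
        assert rec.total_gh2ax == pytest.approx(70.0)
        assert rec.total_dapi == pytest.approx(rec.mean_dapi * rec.area_px, rel=1e-9)
        assert rec.area_um2 == pytest.approx(10 * 0.3225 ** 2)

    def test_empty_label_map_gives_no_records(self):
        dapi, gh = self._channels(np.zeros((4, 4)), np.zeros((4, 4)))
        assert h.measure_nuclei(NucleusLabelMap(np.zeros((4, 4), np.int32)),
                                dapi, gh) == []

    def test_shape_mismatch_rejected(self):
        dapi, _ = self._channels(np.zeros((4, 4)), np.zeros((4, 4)))
        gh = h.ChannelImage(np.zeros((5, 5)), "gh2ax")
        with pytest.raises(ValueError, match="shape"):
            h.measure_nuclei(NucleusLabelMap(np.zeros((4, 4), np.int32)), dapi, gh)

    def test_noise_free_scene_measurements_match_generator_truth(self):
        p = h.SceneParams(n_nuclei=8, seed=21, psf_sigma=0.0,
                          noise_gaussian_sd=0.0, noise_poisson_scale=0.0,
                          gh2ax_positive_fraction=0.4)
        scene = h.generate_scene(p)
        records = h.measure_nuclei(scene.true_labels, scene.dapi, scene.gh2ax)
        truth = {t.label: t for t in scene.nuclei_truth}
        assert len(records) == 8
        for rec in records:
            assert rec.mean_gh2ax == pytest.approx(
                truth[rec.label].true_mean_gh2ax, rel=1e-6)
            assert rec.mean_dapi == pytest.approx(
                truth[rec.label].dapi_level, rel=1e-6)

    def test_totals_additive_under_arbitrary_split(self):
        rng = np.random.default_rng(4)
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[3:9, 3:9] = 1
        img = rng.uniform(0, 100, (12, 12))
        dapi, gh = self._channels(img, img)
        (whole,) = h.measure_nuclei(NucleusLabelMap(labels), dapi, gh)
        split = labels.copy()
        part = rng.random((12, 12)) < 0.5
        split[(labels == 1) & part] = 2
        parts = h.measure_nuclei(NucleusLabelMap(split), dapi, gh)
        assert sum(r.total_dapi for r in parts) == pytest.approx(
            whole.total_dapi, rel=1e-9)
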