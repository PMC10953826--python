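"""Imaging stage: segmentation, shape features, classification, viability."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.measure import euler_number, label as sk_label

from admscreen import (
    RenderParams,
    SegmentationParams,
    classify_objects,
    extract_features,
    render_well_image,
    roundtrip_metrics,
    score_viability,
    segment_objects,
    simulate_well_objects,
)
from admscreen.imaging import train_tree_classifier
from admscreen.simgen import NoiseParams, WellSpec
from conftest import simulate_and_analyze


def make_mask(shape, painter):
    img = np.zeros(shape, dtype=bool)
    painter(img)
    return img


def disk_mask(shape, center, radius):
    def painter(img):
        rr, cc = draw_disk(center, radius, shape=shape)
        img[rr, cc] = True
    return make_mask(shape, painter)


def annulus_mask(shape, center, outer, inner):
    m = disk_mask(shape, center, outer)
    m &= ~disk_mask(shape, center, inner)
    return m


def features_of(mask, green=None):
    labels = sk_label(mask)
    green = green if green is not None else np.zeros(mask.shape)
    objs = extract_features(labels, [mask.astype(float), green])
    assert len(objs) == 1
    return objs[0]


class TestSegmentation:
    def test_rejects_non_2d_input(self):
        with pytest.raises(ValueError, match="2-D"):
            segment_objects(np.zeros((2, 64, 64)))

    def test_background_only_image_yields_no_objects(self):
        truth = simulate_well_objects(
            WellSpec("P1", 0, 0, "VEHICLE", 0.0, "inhibition", 0),
            None, noise=NoiseParams(n_objects_mean=0.0), rng_seed=0)
        image = render_well_image(truth, rng_seed=0)
        labels, objects = segment_objects(image[0])
        assert objects == [] and labels.max() == 0

    def test_merged_disks_stay_one_object(self):
        # no declumping: overlapping footprints are a single component
        m = disk_mask((128, 128), (60, 50), 15) | disk_mask((128, 128),
                                                            (60, 70), 15)
        img = np.where(m, 600.0, 100.0)
        labels, objects = segment_objects(
            img, SegmentationParams(threshold_method="fixed",
                                    fixed_threshold=300.0))
        assert len(objects) == 1

    def test_round_trip_count_on_rendered_well(self):
        spec = WellSpec("P1", 0, 0, "VEHICLE", 0.0, "inhibition", 0)
        truth = simulate_well_objects(spec, None, rng_seed=8)
        image = render_well_image(truth, rng_seed=8)
        _, objects = segment_objects(image[0])
        assert abs(len(objects) - truth.n_objects) <= 2

    def test_border_policy_drop(self):
        img = np.full((128, 128), 100.0)
        rr, cc = draw_disk((0, 64), 15, shape=img.shape)  # touches border
        img[rr, cc] = 600.0
        rr, cc = draw_disk((64, 64), 15, shape=img.shape)
        img[rr, cc] = 600.0
        params = SegmentationParams(threshold_method="fixed",
                                    fixed_threshold=300.0,
                                    border_policy="drop")
        _, objects = segment_objects(img, params)
        assert len(objects) == 1


class TestFeatures:
    def test_filled_disk_features(self):
        obj = features_of(disk_mask((128, 128), (64, 64), 30))
        assert 0.95 <= obj.form_factor <= 1.05
        assert obj.lumen_ratio < 0.02
        assert obj.solidity > 0.95

    def test_annulus_lumen_ratio(self):
        obj = features_of(annulus_mask((128, 128), (64, 64), 30, 15))
        assert 0.22 <= obj.lumen_ratio <= 0.28  # (15/30)^2 = 0.25

    def test_disk_area_closed_form(self):
        obj = features_of(disk_mask((128, 128), (64, 64), 20))
        assert obj.area == pytest.approx(400 * np.pi, rel=0.03)

    def test_dimensionless_features_scale_invariant(self):
        small = features_of(annulus_mask((128, 128), (64, 64), 25, 12))
        big = features_of(annulus_mask((256, 256), (128, 128), 50, 24))
        for name in ("form_factor", "solidity", "eccentricity", "lumen_ratio"):
            assert abs(getattr(small, name) - getattr(big, name)) < 0.05

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            extract_features(np.zeros((64, 64), dtype=int),
                             np.zeros((32, 32)))

    def test_feature_extraction_preserves_object_count(self, analyzed_wells):
        for truth, objects in analyzed_wells:
            labels = {o.object_id for o in objects}
            assert len(labels) == len(objects)


class TestClassification:
    def test_annulus_called_duct_and_berry_called_cluster(self):
        duct = features_of(annulus_mask((128, 128), (64, 64), 30, 15))
        classify_objects([duct])
        assert duct.predicted_class == "duct"
        cluster = features_of(disk_mask((128, 128), (64, 64), 12))
        classify_objects([cluster])
        assert cluster.predicted_class == "cluster"

    def test_missing_features_rejected(self):
        from admscreen.imaging import OrganoidObject
        with pytest.raises(ValueError, match="missing features"):
            classify_objects([OrganoidObject(object_id=1, centroid=(0, 0))])

    def test_rendered_benchmark_accuracy(self, analyzed_wells):
        metrics = roundtrip_metrics(analyzed_wells)
        assert metrics.class_accuracy >= 0.95

    def test_trained_tree_matches_rule_on_rendered_objects(self, analyzed_wells):
        objects = [o for _, objs in analyzed_wells for o in objs]
        rule_labels = [o.predicted_class for o in objects]
        tree = train_tree_classifier(objects, rule_labels)
        relabeled = classify_objects(list(objects), classifier=tree)
        agree = np.mean([o.predicted_class == lab
                         for o, lab in zip(relabeled, rule_labels)])
        assert agree >= 0.98


class TestViability:
    def test_zero_and_saturated_green(self):
        mask = disk_mask((128, 128), (64, 64), 20)
        labels = sk_label(mask)
        objs = extract_features(labels, [mask.astype(float),
                                         np.zeros(mask.shape)])
        score_viability(objs, labels, np.zeros(mask.shape))
        assert objs[0].live is False
        score_viability(objs, labels, np.where(mask, 5000.0, 0.0))
        assert objs[0].live is True

    def test_half_cytotoxic_wells_recover_live_fraction(self):
        from admscreen.simgen import CompoundRecord
        rec = CompoundRecord("TOX", "half lethal", "other", cytotox_frac=0.5)
        pairs = simulate_and_analyze(rec, n_wells=10, seed0=300)
        live = [o.live for _, objs in pairs for o in objs]
        assert 0.45 <= np.mean(live) <= 0.55

    def test_live_accuracy_against_truth(self, analyzed_wells):
        metrics = roundtrip_metrics(analyzed_wells)
        assert metrics.live_accuracy >= 0.98


class TestRendering:
    def test_seed_determinism(self):
        spec = WellSpec("P1", 0, 0, "VEHICLE", 0.0, "inhibition", 0)
        truth = simulate_well_objects(spec, None, rng_seed=4)
        a = render_well_image(truth, rng_seed=4)
        b = render_well_image(truth, rng_seed=4)
        assert np.array_equal(a, b)
        assert a.dtype == np.uint16 and a.shape[0] == 2

    def test_duct_renders_with_hole(self):
        import pandas as pd
        from admscreen.simgen import SimWellTruth
        truth = SimWellTruth(
            spec=WellSpec("P1", 0, 0, "VEHICLE", 0.0, "inhibition", 0),
            frame_shape=(256, 256),
            objects=pd.DataFrame([{"true_class": "duct", "true_live": 1,
                                   "row": 128.0, "col": 128.0,
                                   "radius": 30.0, "lumen_radius": 15.0}]))
        image = render_well_image(truth, RenderParams(noise_sd=(0.0, 0.0)),
                                  rng_seed=0)
        fg = image[0].astype(float) > 300.0
        assert euler_number(fg) < 1  # annulus: one component, one hole

    def test_out_of_frame_object_repositioned_with_warning(self):
        import pandas as pd
        from admscreen.simgen import SimWellTruth
        truth = SimWellTruth(
            spec=WellSpec("P1", 0, 0, "VEHICLE", 0.0, "inhibition", 0),
            frame_shape=(256, 256),
            objects=pd.DataFrame([{"true_class": "duct", "true_live": 1,
                                   "row": 5.0, "col": 5.0,
                                   "radius": 30.0, "lumen_radius": 15.0}]))
        with pytest.warns(UserWarning, match="repositioned"):
            image = render_well_image(truth, rng_seed=0)
        _, objects = segment_objects(image[0])
        assert len(objects) == 1  # never silently dropped
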