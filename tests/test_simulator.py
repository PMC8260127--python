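"""Disk simulator: determinism, ground-truth pairing, box tightness,
annotation projection, dataset generation, and the germination-fraction
statistical contract."""

import numpy as np
import pytest

from germquant.annotations import read_voc_xml, validate_annotation
from germquant.boxes import iou
from germquant.simulate import (
    DatasetManifest,
    DiskSpec,
    generate_dataset,
    radicle_mask,
    render_disk,
    sample_disk,
    seed_mask,
    split_indices,
    truth_to_annotation,
)


class TestSampling:
    def test_exact_count_mode(self, small_truth):
        assert len(small_truth.seeds) == 20
        assert small_truth.n_germinated == 10

    def test_deterministic_given_seed(self, small_spec):
        t1, t2 = sample_disk(small_spec), sample_disk(small_spec)
        assert len(t1.seeds) == len(t2.seeds)
        for a, b in zip(t1.seeds, t2.seeds):
            assert a.center == b.center
            assert a.germinated == b.germinated
            assert a.seed_box == b.seed_box

    def test_zero_germination_has_no_radicles(self):
        spec = DiskSpec(image_size=(256, 256), n_seeds=15,
                        germination_fraction=0.0, rng_seed=1)
        truth = sample_disk(spec)
        assert truth.n_germinated == 0
        assert all(s.radicle_box is None and s.radicle_path is None
                   for s in truth.seeds)

    def test_radicle_present_iff_germinated(self, small_truth):
        for s in small_truth.seeds:
            assert (s.radicle_path is not None) == s.germinated
            assert (s.radicle_box is not None) == s.germinated

    def test_boxes_within_image_bounds(self, small_truth):
        w, h = small_truth.spec.image_size
        for s in small_truth.seeds:
            for box in filter(None, (s.seed_box, s.radicle_box)):
                assert 0 <= box.xmin < box.xmax <= w
                assert 0 <= box.ymin < box.ymax <= h

    def test_infeasible_packing_raises(self):
        spec = DiskSpec(image_size=(96, 96), n_seeds=500, rng_seed=0)
        with pytest.raises(RuntimeError, match="packing"):
            sample_disk(spec)

    def test_default_seed_count_in_assay_range(self):
        for seed in range(5):
            truth = sample_disk(DiskSpec(rng_seed=seed))
            assert 50 <= len(truth.seeds) <= 100

    def test_germination_fraction_statistical_contract(self):
        """Pooled germinated fraction over 200 disks within 3 binomial SE
        of the nominal 0.55."""
        p = 0.55
        germ = total = 0
        for seed in range(200):
            spec = DiskSpec(germination_fraction=p, rng_seed=seed)
            truth = sample_disk(spec)
            germ += truth.n_germinated
            total += len(truth.seeds)
        se = np.sqrt(p * (1 - p) / total)
        assert abs(germ / total - p) < 3 * se

    def test_validation_rejects_bad_spec(self):
        with pytest.raises(ValueError):
            DiskSpec(germination_fraction=1.5).validate()
        with pytest.raises(ValueError):
            DiskSpec(seed_axis_range=(10.0, 5.0)).validate()


class TestRendering:
    def test_pure_function_of_truth(self, small_truth):
        img1, img2 = render_disk(small_truth), render_disk(small_truth)
        assert img1.dtype == np.uint8
        np.testing.assert_array_equal(img1, img2)

    def test_seeds_darker_than_disk(self, small_truth):
        img = render_disk(small_truth).astype(float).mean(axis=2)
        h, w = img.shape
        disk_center = img[h // 2 - 10 : h // 2 + 10, w // 2 - 10 : w // 2 + 10]
        for s in small_truth.seeds[:5]:
            m = seed_mask(s, img.shape)
            assert img[m].mean() < disk_center.mean() - 20

    def test_zero_contrast_hides_radicles(self, small_spec):
        truth = sample_disk(small_spec)
        spec0 = DiskSpec.from_dict({**small_spec.to_dict(), "radicle_contrast": 0.0})
        truth0 = sample_disk(spec0)
        img0 = render_disk(truth0)
        # same geometry with radicles stripped renders identically
        for s in truth0.seeds:
            s.radicle_path = None
        np.testing.assert_array_equal(render_disk(truth0), img0)

    def test_boxes_tight_against_rendered_masks(self, small_truth):
        """Every ground-truth box has IoU 1.0 with the tight box recomputed
        from its object's own pixel mask."""
        from germquant.boxes import mask_to_box

        shape = small_truth.spec.image_size[::-1]
        for s in small_truth.seeds:
            assert iou(s.seed_box, mask_to_box(seed_mask(s, shape))) == 1.0
            if s.germinated:
                assert iou(s.radicle_box, mask_to_box(radicle_mask(s, shape))) == 1.0

    def test_protuberance_only_on_non_germinated(self):
        spec = DiskSpec(image_size=(256, 256), n_seeds=30,
                        protuberance_probability=1.0, rng_seed=3)
        truth = sample_disk(spec)
        assert any(s.protuberance for s in truth.seeds)
        assert all(not s.protuberance or not s.germinated for s in truth.seeds)


class TestAnnotationProjection:
    def test_s_r_box_counts(self, small_truth):
        ann = truth_to_annotation(small_truth, "S_R")
        labels = [lab for lab, _ in ann.objects]
        assert labels.count("S") == 20
        assert labels.count("R") == 10

    def test_ngs_gs_box_counts(self, small_truth):
        ann = truth_to_annotation(small_truth, "NGS_GS")
        labels = [lab for lab, _ in ann.objects]
        assert labels.count("NGS") == 10
        assert labels.count("GS") == 10
        assert len(ann.objects) == 20

    def test_gs_box_contains_seed_box(self, small_truth):
        ann = truth_to_annotation(small_truth, "NGS_GS")
        gs_boxes = ann.boxes_of("GS")
        germ = [s for s in small_truth.seeds if s.germinated]
        for s, gs in zip(germ, gs_boxes):
            assert gs.xmin <= s.seed_box.xmin and gs.xmax >= s.seed_box.xmax
            assert gs.ymin <= s.seed_box.ymin and gs.ymax >= s.seed_box.ymax

    def test_projection_passes_validation(self, small_truth):
        for scheme in ("S_R", "NGS_GS"):
            assert validate_annotation(truth_to_annotation(small_truth, scheme)) == []


class TestDatasetGeneration:
    def test_split_proportions_60_20_20(self):
        assert split_indices(10) == ["train"] * 6 + ["val"] * 2 + ["test"] * 2
        # the full-scale census: 161 images -> 97/32/32
        s = split_indices(161)
        assert (s.count("train"), s.count("val"), s.count("test")) == (97, 32, 32)

    def test_generated_files_parse_and_validate(self, tiny_dataset):
        assert len(tiny_dataset.entries) == 10
        for image_id in tiny_dataset.ids():
            ann = read_voc_xml(tiny_dataset.xml_path(image_id), expected_scheme="S_R")
            assert validate_annotation(ann) == []
            assert tiny_dataset.image_path(image_id).exists()

    def test_manifest_round_trip(self, tiny_dataset):
        loaded = DatasetManifest.load(tiny_dataset.root / "manifest.csv")
        assert loaded.entries == tiny_dataset.entries

    def test_regeneration_is_byte_identical(self, tmp_path):
        spec = DiskSpec(image_size=(192, 192), n_seeds=12, rng_seed=5)
        generate_dataset(spec, 3, "NGS_GS", tmp_path / "a")
        generate_dataset(spec, 3, "NGS_GS", tmp_path / "b")
        for rel in ["manifest.csv", "images/disk_0001.png", "annotations/disk_0001.xml"]:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()
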