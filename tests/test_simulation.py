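"""Simulated synapse image generator and recall/precision scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest

from punctacoloc import (
    SimulationConfig,
    gaussian_background,
    generate_benchmark_set,
    generate_simulated_image,
    make_templates,
    match_and_score,
)


class TestTemplates:
    def test_deterministic_given_seed(self, small_sim_config):
        t1 = make_templates(small_sim_config)
        t2 = make_templates(small_sim_config)
        for ch in ("red", "green"):
            assert len(t1[ch]) == small_sim_config.n_templates_per_channel
            for a, b in zip(t1[ch], t2[ch]):
                np.testing.assert_array_equal(a.stamp, b.stamp)

    def test_degenerate_ranges_give_identical_stamps(self):
        config = SimulationConfig(
            width=64,
            height=64,
            n_positions=3,
            n_red_only=1,
            n_green_only=1,
            n_both=1,
            template_radius_range=(3, 3),
            template_peak_range=(200, 200),
        )
        templates = make_templates(config)
        for ch in ("red", "green"):
            for t in templates[ch]:
                np.testing.assert_array_equal(t.stamp, templates["red"][0].stamp)

    def test_peak_is_stamp_maximum(self, small_sim_config):
        for ch_templates in make_templates(small_sim_config).values():
            for t in ch_templates:
                assert int(t.stamp.max()) == t.peak
                assert t.stamp.sum() > 0


class TestBackground:
    def test_multiplier_zero_is_black(self):
        assert gaussian_background(64, 64, 20, 12, 0.0, seed=5).max() == 0

    def test_sample_mean_near_target(self):
        plane = gaussian_background(1024, 1024, 20, 12, 1.0, seed=3)
        n = 1024 * 1024
        assert abs(plane.mean() - 20) < 3 * 12 / np.sqrt(n) + 0.5  # CLT + rounding slack

    def test_seed_reproducible(self):
        a = gaussian_background(32, 32, 20, 12, 0.5, seed=11)
        b = gaussian_background(32, 32, 20, 12, 0.5, seed=11)
        np.testing.assert_array_equal(a, b)


class TestGenerateImage:
    def test_class_counts_match_config(self, small_sim_config):
        _, truth = generate_simulated_image(small_sim_config, 0.25, seed=42)
        assert truth.n_red == 20  # red_only + both
        assert truth.n_green == 20
        assert truth.n_both == 10

    def test_minimal_allocation(self):
        config = SimulationConfig(
            width=128, height=128, n_positions=3, n_red_only=1, n_green_only=1, n_both=1
        )
        _, truth = generate_simulated_image(config, 0.0, seed=1)
        assert [truth.n_red, truth.n_green, truth.n_both] == [2, 2, 1]

    def test_same_seed_identical(self, small_sim_config):
        img1, truth1 = generate_simulated_image(small_sim_config, 0.5, seed=9)
        img2, truth2 = generate_simulated_image(small_sim_config, 0.5, seed=9)
        for role in ("red", "green"):
            np.testing.assert_array_equal(img1.planes[role], img2.planes[role])
        assert truth1.to_frame().equals(truth2.to_frame())

    def test_same_channel_boxes_disjoint(self, small_sim_config):
        _, truth = generate_simulated_image(small_sim_config, 0.0, seed=13)
        for channel, size_attr in (("red", "size_red"), ("green", "size_green")):
            occupancy = np.zeros((256, 256), dtype=int)
            for e in truth.entries:
                s = getattr(e, size_attr)
                if s is not None:
                    occupancy[e.y : e.y + s, e.x : e.x + s] += 1
            assert occupancy.max() == 1

    def test_puncta_actually_pasted(self, small_sim_config):
        img, truth = generate_simulated_image(small_sim_config, 0.0, seed=21)
        for e in truth.entries:
            if e.size_red is not None:
                assert img.planes["red"][e.y : e.y + e.size_red, e.x : e.x + e.size_red].max() > 0
            if e.size_green is not None:
                assert (
                    img.planes["green"][e.y : e.y + e.size_green, e.x : e.x + e.size_green].max()
                    > 0
                )

    def test_impossible_packing_raises(self):
        config = SimulationConfig(
            width=16,
            height=16,
            n_positions=200,
            n_red_only=100,
            n_green_only=50,
            n_both=50,
            template_radius_range=(3, 3),
        )
        with pytest.raises(RuntimeError, match="larger image"):
            generate_simulated_image(config, 0.0, seed=0)

    def test_invalid_allocation_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(n_positions=10, n_red_only=5, n_green_only=5, n_both=5)


class TestBenchmarkSet:
    def test_manifest_bookkeeping(self, small_sim_config, tmp_path):
        manifest = generate_benchmark_set(small_sim_config, tmp_path / "bench")
        assert len(manifest) == 4  # 2 levels x 2 images
        assert manifest.groupby("multiplier").size().tolist() == [2, 2]
        for fname in manifest["file"]:
            assert (tmp_path / "bench" / fname).exists()
            assert (tmp_path / "bench" / fname.replace(".tif", "_truth.csv")).exists()
        on_disk = pd.read_csv(tmp_path / "bench" / "manifest.csv")
        assert on_disk["file"].tolist() == manifest["file"].tolist()

    def test_single_image_set(self, tmp_path):
        config = SimulationConfig(
            width=128,
            height=128,
            n_positions=6,
            n_red_only=2,
            n_green_only=2,
            n_both=2,
            noise_multipliers=(0.0,),
            n_images_per_level=1,
        )
        manifest = generate_benchmark_set(config, tmp_path / "one")
        assert len(manifest) == 1

    def test_images_reproducible_from_manifest(self, small_sim_config, tmp_path):
        import tifffile

        manifest = generate_benchmark_set(small_sim_config, tmp_path / "bench")
        row = manifest.iloc[0]
        img, _ = generate_simulated_image(
            small_sim_config, row["multiplier"], int(row["seed"])
        )
        stored = tifffile.imread(tmp_path / "bench" / row["file"])
        np.testing.assert_array_equal(stored, img.to_array())


class TestMatchAndScore:
    def test_perfect_detections(self, small_sim_config):
        _, truth = generate_simulated_image(small_sim_config, 0.0, seed=3)
        result = match_and_score(truth.both_centers(), truth)
        assert result == {
            "tp": truth.n_both,
            "fp": 0,
            "fn": 0,
            "recall": 1.0,
            "precision": 1.0,
        }

    def test_no_detections(self):
        truth = np.array([[5.0, 5.0]] * 333)
        result = match_and_score(np.empty((0, 2)), truth)
        assert result["fn"] == 333 and result["recall"] == 0.0 and result["precision"] == 1.0

    def test_two_truths_three_detections(self):
        truth = np.array([[10.0, 10.0], [30.0, 30.0]])
        detections = np.array([[11.0, 10.0], [29.0, 30.0], [50.0, 50.0]])
        result = match_and_score(detections, truth, tolerance=5.0)
        assert (result["tp"], result["fp"], result["fn"]) == (2, 1, 0)
        assert result["recall"] == 1.0
        assert result["precision"] == pytest.approx(2 / 3)
        # brute force over all one-to-one assignments confirms 2 is the max
        best = 0
        for perm in itertools.permutations(range(3), 2):
            matches = sum(
                1
                for t, d in enumerate(perm)
                if np.linalg.norm(detections[d] - truth[t]) <= 5.0
            )
            best = max(best, matches)
        assert best == result["tp"]

    def test_greedy_is_one_to_one(self):
        truth = np.array([[0.0, 0.0]])
        detections = np.array([[1.0, 0.0], [2.0, 0.0]])
        result = match_and_score(detections, truth, tolerance=5.0)
        assert (result["tp"], result["fp"], result["fn"]) == (1, 1, 0)

    def test_bookkeeping_identities(self, rng):
        truth = rng.uniform(0, 100, (20, 2))
        detections = rng.uniform(0, 100, (35, 2))
        result = match_and_score(detections, truth, tolerance=4.0)
        assert result["tp"] + result["fn"] == 20
        assert result["tp"] + result["fp"] == 35

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            match_and_score(np.empty((0, 2)), np.empty((0, 2)), tolerance=0)
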