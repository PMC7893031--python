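"""Synthetic image generation, nucleus segmentation and coverage."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk

from cardiomea.imaging import (
    SegmentationParams,
    nucleus_areas,
    sarcomere_coverage,
    sarcomere_mask_from_texture,
    segment_nuclei,
    synth_coverage_image,
    synth_nucleus_image,
)

PX = 0.05  # um/px used throughout


def disk_image(shape=(300, 300), center=(150, 150), radius=40, noise_sd=0.02, seed=0):
    img = np.zeros(shape)
    rr, cc = disk(center, radius, shape=shape)
    img[rr, cc] = 1.0
    img = ndi.gaussian_filter(img, 1.5)
    rng = np.random.default_rng(seed)
    return img + noise_sd * rng.standard_normal(shape)


class TestSynthNucleusImage:
    def test_zero_nuclei_blank_channel(self):
        img = synth_nucleus_image(0, noise_sd=0.0, rng=0)
        assert img.nucleus_channel.max() == 0.0
        assert img.nuclei == []

    def test_ground_truth_area_is_pi_a_b(self):
        img = synth_nucleus_image(5, clump_fraction=0.0, rng=1)
        for nuc in img.nuclei:
            a_px, b_px = nuc.semi_axes_px
            assert nuc.area_um2 == pytest.approx(np.pi * a_px * b_px * PX**2)

    def test_population_mean_near_target(self):
        img = synth_nucleus_image(60, mean_area_um2=35.7, clump_fraction=0.0, rng=2)
        truth = np.array([n.area_um2 for n in img.nuclei])
        assert truth.mean() == pytest.approx(35.7, rel=0.25)

    def test_seeded_reproducibility(self):
        a = synth_nucleus_image(20, rng=5)
        b = synth_nucleus_image(20, rng=5)
        assert np.array_equal(a.nucleus_channel, b.nucleus_channel)


class TestSegmentNuclei:
    def test_single_disk_counted_once_with_correct_area(self):
        radius = 40
        objs, acc = segment_nuclei(disk_image(radius=radius), PX)
        assert acc["kept"] == len(objs) == 1
        assert objs[0].pixel_count == pytest.approx(np.pi * radius**2, rel=0.1)

    def test_border_touching_disk_discarded(self):
        img = disk_image(center=(10, 150))  # overlaps the top border
        objs, acc = segment_nuclei(img, PX)
        assert objs == []
        assert acc["border_filtered"] >= 1

    def test_out_of_bounds_sizes_filtered(self):
        small = disk_image(radius=10)  # equivalent diameter 20 px < 50
        objs, acc = segment_nuclei(small, PX)
        assert objs == []
        assert acc["size_filtered"] == 1

    def test_two_overlapping_disks_declumped(self):
        img = np.zeros((300, 300))
        for center in ((150, 120), (150, 192)):  # 8 px overlap of 40 px radii
            rr, cc = disk(center, 40, shape=img.shape)
            img[rr, cc] = 1.0
        img = ndi.gaussian_filter(img, 1.5)
        objs, acc = segment_nuclei(img, PX)
        assert acc["kept"] == 2

    def test_constant_image_degenerate(self):
        objs, acc = segment_nuclei(np.zeros((64, 64)), PX)
        assert objs == [] and acc["degenerate"]

    def test_accounting_identity_on_synthetic_population(self):
        img = synth_nucleus_image(40, clump_fraction=0.1, rng=7)
        _, acc = segment_nuclei(img.nucleus_channel, PX)
        assert acc["detected"] == acc["kept"] + acc["size_filtered"] + acc["border_filtered"]

    def test_recall_and_area_error_on_clean_fixture(self):
        """>= 95% recall, per-object area error <= 10% for isolated nuclei at high SNR."""
        img = synth_nucleus_image(40, clump_fraction=0.0, noise_sd=0.05, rng=11)
        objs, _ = segment_nuclei(img.nucleus_channel, PX)
        truth = img.nuclei
        assert len(objs) >= 0.95 * len(truth)
        centers = np.array([o.centroid_px for o in objs])
        for nuc in truth:
            d = np.hypot(centers[:, 0] - nuc.center_px[0], centers[:, 1] - nuc.center_px[1])
            j = int(np.argmin(d))
            if d[j] < max(nuc.semi_axes_px):
                assert objs[j].area_um2 == pytest.approx(nuc.area_um2, rel=0.10)


class TestNucleusAreas:
    def test_area_arithmetic(self):
        from cardiomea.imaging import NucleusObject

        obj = NucleusObject(1, 100, 0.0, (0, 0), False)
        areas, summary = nucleus_areas([obj], pixel_size_um=0.5)
        assert areas[0] == pytest.approx(25.0)
        assert summary["n"] == 1


class TestSarcomereCoverage:
    def test_full_coverage_is_100(self):
        mask = np.ones((10, 10), bool)
        assert sarcomere_coverage(mask, mask) == 100.0

    def test_half_covered_rectangle(self):
        cell = np.ones((10, 20), bool)
        sarc = np.zeros_like(cell)
        sarc[:, :10] = True
        assert sarcomere_coverage(sarc, cell) == pytest.approx(50.0)

    def test_empty_cell_mask_is_zero(self):
        assert sarcomere_coverage(np.ones((5, 5), bool), np.zeros((5, 5), bool)) == 0.0

    def test_sarcomere_outside_cell_ignored(self):
        cell = np.zeros((10, 10), bool)
        cell[:5] = True
        sarc = np.ones((10, 10), bool)
        assert sarcomere_coverage(sarc, cell) == pytest.approx(100.0)

    def test_invariant_under_common_rescaling(self):
        img = synth_coverage_image(0.6, rng=3)
        base = sarcomere_coverage(img.sarcomere_mask, img.cell_mask)
        zoomed_s = np.kron(img.sarcomere_mask, np.ones((2, 2), bool))
        zoomed_c = np.kron(img.cell_mask, np.ones((2, 2), bool))
        assert sarcomere_coverage(zoomed_s, zoomed_c) == pytest.approx(base)

    def test_generator_fraction_recovered(self):
        img = synth_coverage_image(0.694, rng=4)
        assert img.true_coverage_percent == pytest.approx(69.4, abs=0.5)

    def test_texture_mask_approximates_truth(self):
        img = synth_coverage_image(0.5, shape=(256, 256), noise_sd=0.02, rng=5)
        est = sarcomere_mask_from_texture(img.sarcomere_channel)
        inter = (est & img.sarcomere_mask).sum()
        union = (est | img.sarcomere_mask).sum()
        assert inter / union > 0.5
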