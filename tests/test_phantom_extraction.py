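"""Phantom rasterization and two-step HU-threshold extraction."""

from __future__ import annotations

import math

import numpy as np
import pytest

from plaquegeom.mesh_synthesis import make_calcification
from plaquegeom.phantom_extraction import (
    DEFAULT_HU,
    HUInterval,
    ROI,
    ThresholdConfig,
    VoxelPhantom,
    components_to_mesh,
    dice_coefficient,
    extract_two_step,
    extraction_error_report,
    load_phantom,
    rasterize,
    save_phantom,
)

SPHERE_VOL = 4 * math.pi * 8 / 3  # radius-2 sphere


@pytest.fixture(scope="module")
def sphere_phantom() -> VoxelPhantom:
    """One radius-2 calcified sphere at 0.25 mm spacing, no degradation."""
    blob = make_calcification((8, 8, 8), (2, 2, 2), 0.0, seed=1, subdivisions=4)
    return rasterize([(blob, "calcified")], (64, 64, 64), 0.25, (0.06, 0.06, 0.06))


class TestRasterize:
    def test_sphere_volume(self, sphere_phantom):
        vol = (sphere_phantom.truth_labels > 0).sum() * sphere_phantom.voxel_volume
        assert vol == pytest.approx(SPHERE_VOL, rel=0.05)

    def test_empty_scene_is_background(self):
        ph = rasterize([], (8, 8, 8), 1.0)
        assert np.all(ph.hu == DEFAULT_HU["background"])
        assert np.all(ph.truth_labels == 0)

    def test_noise_deterministic_for_seed(self):
        blob = make_calcification((4, 4, 4), (1.5, 1.5, 1.5), 0.0, seed=0)
        args = dict(shape=(32, 32, 32), spacing=0.25, origin=(0.1, 0.1, 0.1),
                    noise_sd=15.0)
        a = rasterize([(blob, "calcified")], seed=42, **args)
        b = rasterize([(blob, "calcified")], seed=42, **args)
        assert np.array_equal(a.hu, b.hu)
        c = rasterize([(blob, "calcified")], seed=43, **args)
        assert not np.array_equal(a.hu, c.hu)

    def test_priority_order(self):
        """Calcification embedded in plaque wins the overlapping voxels."""
        outer = make_calcification((4, 4, 4), (2.5, 2.5, 2.5), 0.0, seed=0)
        inner = make_calcification((4, 4, 4), (1.0, 1.0, 1.0), 0.0, seed=0)
        ph = rasterize(
            [(inner, "calcified"), (outer, "noncalcified")], (32, 32, 32), 0.25,
            (0.1, 0.1, 0.1),
        )
        assert (ph.truth_labels == 3).sum() > 0
        assert (ph.truth_labels == 2).sum() > 0
        inner_vol = (ph.truth_labels == 3).sum() * ph.voxel_volume
        assert inner_vol == pytest.approx(4 * math.pi / 3, rel=0.08)


class TestThresholds:
    def test_interval_convention(self):
        cfg = ThresholdConfig()
        hu = np.array([[[0.0, 150.0, 150.5, 1334.0]]])
        ph = VoxelPhantom(hu=hu, spacing=(1, 1, 1))
        calc, noncalc, _ = extract_two_step(ph, cfg=cfg)
        nc_mask = np.zeros_like(hu, dtype=bool)
        for comp in noncalc:
            nc_mask |= comp.mask
        c_mask = np.zeros_like(hu, dtype=bool)
        for comp in calc:
            c_mask |= comp.mask
        # 0 HU excluded; exactly 150 HU is non-calcified; above 150 calcified
        assert not nc_mask[0, 0, 0]
        assert nc_mask[0, 0, 1]
        assert c_mask[0, 0, 2]
        assert c_mask[0, 0, 3]

    def test_masks_disjoint(self, sphere_phantom):
        calc, noncalc, _ = extract_two_step(sphere_phantom)
        c = np.zeros(sphere_phantom.hu.shape, dtype=bool)
        for comp in calc:
            c |= comp.mask
        n = np.zeros_like(c)
        for comp in noncalc:
            n |= comp.mask
        assert not np.any(c & n)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            ThresholdConfig(
                noncalcified=HUInterval(0, 200), calcified=HUInterval(150, 1334)
            )

    def test_roi_restricts_extraction(self, sphere_phantom):
        calc_all, _, _ = extract_two_step(sphere_phantom)
        roi = ROI((0, 0, 0), (8, 8, 8))  # corner away from the sphere
        calc_roi, _, _ = extract_two_step(sphere_phantom, roi=roi)
        assert len(calc_all) == 1
        assert len(calc_roi) == 0


class TestComponents:
    def test_single_sphere_single_component(self, sphere_phantom):
        calc, _, outer = extract_two_step(sphere_phantom)
        assert len(calc) == 1
        assert calc[0].volume_mm3 == pytest.approx(SPHERE_VOL, rel=0.05)
        assert outer.sum() >= calc[0].voxel_count

    def test_two_separated_spheres(self):
        a = make_calcification((3, 3, 3), (1, 1, 1), 0.0, seed=0)
        b = make_calcification((9, 9, 9), (1, 1, 1), 0.0, seed=0)
        ph = rasterize(
            [(a, "calcified"), (b, "calcified")], (48, 48, 48), 0.25, (0.1, 0.1, 0.1)
        )
        calc, _, _ = extract_two_step(ph)
        assert len(calc) == 2

    def test_component_to_mesh_roundtrip(self, sphere_phantom):
        calc, _, _ = extract_two_step(sphere_phantom)
        mesh = components_to_mesh(calc[0], sphere_phantom.spacing, sphere_phantom.origin)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(SPHERE_VOL, rel=0.05)
        assert np.allclose(mesh.center_mass, [8.0, 8.0, 8.0], atol=0.25)


class TestErrorReport:
    def test_truth_against_itself(self, sphere_phantom):
        calc, _, _ = extract_two_step(sphere_phantom)
        truth = sphere_phantom.truth_labels == 3
        report = extraction_error_report(
            calc, [truth], sphere_phantom.voxel_volume,
            sphere_phantom.spacing, sphere_phantom.origin,
        )
        assert report.loc[0, "dice"] == pytest.approx(1.0)
        assert report.loc[0, "rel_volume_error"] == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_extraction_high_dice(self):
        blob = make_calcification((6, 6, 6), (2, 1.5, 1.2), 0.2, seed=9, subdivisions=4)
        ph = rasterize([(blob, "calcified")], (48, 48, 48), 0.25, (0.1, 0.1, 0.1))
        calc, _, _ = extract_two_step(ph)
        report = extraction_error_report(
            calc, [ph.truth_labels == 3], ph.voxel_volume, ph.spacing, ph.origin
        )
        assert (report["dice"] > 0.95).all()

    def test_blooming_inflates_calcification(self):
        blob = make_calcification((6, 6, 6), (2, 2, 2), 0.0, seed=0, subdivisions=4)
        sharp = rasterize([(blob, "calcified")], (48, 48, 48), 0.25, (0.1, 0.1, 0.1))
        blurred = rasterize(
            [(blob, "calcified")], (48, 48, 48), 0.25, (0.1, 0.1, 0.1),
            blooming_sigma=0.5,
        )
        v_sharp = sum(c.volume_mm3 for c in extract_two_step(sharp)[0])
        v_blur = sum(c.volume_mm3 for c in extract_two_step(blurred)[0])
        assert v_blur >= v_sharp

    def test_dice_identities(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[1:3, 1:3, 1:3] = True
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, ~a) == 0.0


def test_nifti_roundtrip(tmp_path, sphere_phantom):
    hu_path = tmp_path / "phantom.nii.gz"
    lab_path = tmp_path / "labels.nii.gz"
    save_phantom(sphere_phantom, hu_path, lab_path)
    back = load_phantom(hu_path, lab_path)
    assert np.allclose(back.hu, sphere_phantom.hu, atol=1e-3)
    assert np.array_equal(back.truth_labels, sphere_phantom.truth_labels)
    assert back.spacing == pytest.approx(sphere_phantom.spacing)
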