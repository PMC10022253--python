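"""Segmentation, voxel volumetry, and the clock-face quadrant partition."""

import numpy as np
import pytest

from glenovol import (EmptySegmentationError, Quadrant, ScapularLandmarks,
                      SegmentationMask, VolumeImage, build_frame, classify_quadrant,
                      quadrant_label_map, quadrant_volumes, segment_contrast,
                      total_volume)
from glenovol.errors import GeometryError, PlausibilityWarning
from glenovol.simulate import PhantomSpec, make_phantom

from conftest import random_rotation


def _dice(a, b):
    a, b = a.astype(bool), b.astype(bool)
    return 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


# ---------------------------------------------------------------- segmentation

def test_uniform_bright_volume_fully_labeled():
    vol = VolumeImage(voxels=np.full((6, 6, 6), 200.0), spacing=1.0)
    mask = segment_contrast(vol, seed_mm=[2.0, 2.0, 2.0], threshold=100.0)
    assert mask.n_labeled == 6 ** 3
    assert mask.same_geometry(vol)


def test_two_disjoint_blobs_only_seeded_one_labeled():
    ph = make_phantom(PhantomSpec(shape="two_blob", radius_mm=10.0,
                                  blob2_center_mm=[0.0, 20.0, 0.0],
                                  blob2_radius_mm=6.0, noise_sd=0.0), rng=0)
    mask = segment_contrast(ph.volume, ph.seed_point_mm, ph.spec.mid_contrast)
    sphere1_ml = 4 / 3 * np.pi * 10.0 ** 3 / 1000
    assert abs(total_volume(mask) - sphere1_ml) / sphere1_ml < 0.02
    assert mask.n_labeled < ph.mask.n_labeled  # blob 2 untouched


def test_noisy_phantom_dice_against_ground_truth(noisy_sphere_phantom):
    ph = noisy_sphere_phantom
    mask = segment_contrast(ph.volume, ph.seed_point_mm, ph.spec.mid_contrast)
    assert _dice(mask.voxels, ph.mask.voxels) >= 0.99


def test_seed_below_threshold_raises():
    vol = VolumeImage(voxels=np.zeros((5, 5, 5)), spacing=1.0)
    with pytest.raises(EmptySegmentationError, match="threshold"):
        segment_contrast(vol, seed_mm=[2, 2, 2], threshold=10.0)


def test_seed_outside_grid_raises():
    vol = VolumeImage(voxels=np.zeros((5, 5, 5)), spacing=1.0)
    with pytest.raises(GeometryError, match="outside"):
        segment_contrast(vol, seed_mm=[50, 0, 0], threshold=0.0)


# ------------------------------------------------------------------ volumetry

def test_total_volume_unit_conversion():
    vox = np.zeros((10, 10, 10), dtype=np.uint8)
    vox.flat[:1000] = 1
    assert total_volume(SegmentationMask(voxels=vox, spacing=1.0)) == pytest.approx(1.0)
    full = SegmentationMask(voxels=np.ones((10, 10, 10), np.uint8), spacing=2.0)
    assert total_volume(full) == pytest.approx(8.0)


def test_sphere_volume_within_1pct_of_analytic_at_half_mm():
    ph = make_phantom(PhantomSpec(radius_mm=20.0, spacing_mm=0.5,
                                  grid_shape=(88, 88, 88), noise_sd=0.0), rng=0)
    analytic = 4 / 3 * np.pi * 20.0 ** 3 / 1000  # 33.51 mL
    assert abs(total_volume(ph.mask) - analytic) / analytic < 0.01


def test_resolution_convergence():
    """Voxelization error shrinks as spacing decreases."""
    errs = {}
    for sp, dims in ((2.0, (26, 26, 26)), (1.0, (48, 48, 48)), (0.5, (88, 88, 88))):
        ph = make_phantom(PhantomSpec(radius_mm=20.0, spacing_mm=sp,
                                      grid_shape=dims, noise_sd=0.0), rng=0)
        errs[sp] = abs(total_volume(ph.mask) - ph.analytic.total) / ph.analytic.total
    assert errs[0.5] < errs[2.0]


# ------------------------------------------------------------------ quadrants

@pytest.mark.parametrize("a,s,expected", [
    (1.0, -1.0, Quadrant.AIQ),    # 6-9 h anteroinferior
    (1.0, 1.0, Quadrant.ASQ),     # 9-12 h anterosuperior
    (-1.0, 1.0, Quadrant.PSQ),    # 12-3 h posterosuperior
    (-1.0, -1.0, Quadrant.PIQ),   # 3-6 h posteroinferior
    (1.0, 0.0, Quadrant.ASQ),     # 9 h ray starts ASQ
    (0.0, 1.0, Quadrant.PSQ),     # 12 h ray starts PSQ
    (-1.0, 0.0, Quadrant.PIQ),    # 3 h ray starts PIQ
    (0.0, -1.0, Quadrant.AIQ),    # 6 h ray starts AIQ
    (0.0, 0.0, Quadrant.PSQ),     # origin assigned to PSQ
])
def test_classify_quadrant_half_open_clock(a, s, expected):
    assert classify_quadrant(a, s) is expected


def test_classify_rejects_non_finite():
    with pytest.raises(ValueError):
        classify_quadrant(np.nan, 0.0)


def test_centered_shell_quadrants_equal(shell_phantom):
    qv = quadrant_volumes(shell_phantom.mask, shell_phantom.frame)
    for q in (qv.aiq, qv.asq, qv.psq, qv.piq):
        assert abs(q - qv.total / 4) <= 0.01 * qv.total


def test_offset_sphere_anterior_matches_cap_formula():
    """Sphere center 5 mm anterior: anterior half = the larger spherical cap."""
    R, d = 20.0, 5.0
    ph = make_phantom(PhantomSpec(shape="offset_sphere", radius_mm=R,
                                  offset_mm=[d, 0.0, 0.0], noise_sd=0.0), rng=0)
    qv = quadrant_volumes(ph.mask, ph.frame)
    h = R + d
    cap_ml = np.pi * h * h * (3 * R - h) / 3 / 1000
    anterior = qv.aiq + qv.asq
    assert abs(anterior - cap_ml) / cap_ml < 0.02
    # brute-force voxel oracle: count ground-truth voxels with a > 0
    coords = ph.frame.to_coords(ph.mask.labeled_centers_mm())
    brute_ml = np.count_nonzero(coords[:, 0] > 0) * ph.mask.voxel_volume_mm3 / 1000
    assert anterior == pytest.approx(brute_ml, abs=ph.mask.voxel_volume_mm3 / 1000)
    # generator's own analytic split agrees
    assert ph.analytic.aiq + ph.analytic.asq == pytest.approx(cap_ml, rel=1e-12)


def test_empty_mask_gives_zero_volumes(baseline_frame):
    mask = SegmentationMask(voxels=np.zeros((5, 5, 5), np.uint8), spacing=1.0,
                            origin=baseline_frame.origin - 2)
    qv = quadrant_volumes(mask, baseline_frame)
    assert (qv.total, qv.aiq, qv.asq, qv.psq, qv.piq) == (0, 0, 0, 0, 0)


def test_conservation_random_masks_and_frames():
    """AIQ+ASQ+PSQ+PIQ equals the total exactly for arbitrary masks/frames."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        vox = (rng.random((12, 12, 12)) > 0.6).astype(np.uint8)
        R = random_rotation(rng, np.deg2rad(25))
        lm = ScapularLandmarks([0, 0, 0], [0, 0, 100], [60, 0, 80]).transformed(
            R, rng.uniform(-10, 10, 3))
        mask = SegmentationMask(voxels=vox, spacing=rng.uniform(0.5, 2.0),
                                origin=lm.glenoid_center - 6)
        qv = quadrant_volumes(mask, build_frame(lm))
        assert qv.quadrant_sum == pytest.approx(qv.total, abs=0)


def test_far_frame_origin_warns(baseline_frame):
    mask = SegmentationMask(voxels=np.ones((4, 4, 4), np.uint8), spacing=1.0,
                            origin=baseline_frame.origin + 400.0)
    with pytest.warns(PlausibilityWarning):
        quadrant_volumes(mask, baseline_frame)


def test_rigid_motion_invariance(sphere_phantom):
    """Transforming image geometry and landmarks together leaves volumes alone."""
    ph = sphere_phantom
    qv0 = quadrant_volumes(ph.mask, ph.frame)
    rng = np.random.default_rng(7)
    for _ in range(3):
        R = random_rotation(rng, np.deg2rad(25))
        t = rng.uniform(-30, 30, 3)
        moved_mask = SegmentationMask(voxels=ph.mask.voxels.copy(),
                                      spacing=ph.mask.spacing.copy(),
                                      origin=R @ ph.mask.origin + t,
                                      direction=R @ ph.mask.direction)
        moved_frame = build_frame(ph.landmarks.transformed(R, t))
        qv = quadrant_volumes(moved_mask, moved_frame)
        assert qv.total == pytest.approx(qv0.total, abs=0)
        for attr in ("aiq", "asq", "psq", "piq"):
            assert getattr(qv, attr) == pytest.approx(getattr(qv0, attr),
                                                      rel=0.01)


def test_mirror_left_right_symmetry():
    """A left-shoulder phantom yields the same quadrant volumes as its right mirror."""
    right = make_phantom(PhantomSpec(shape="offset_sphere", radius_mm=15.0,
                                     offset_mm=[4.0, 3.0, 0.0], noise_sd=0.0), rng=0)
    left_spec = PhantomSpec(shape="offset_sphere", radius_mm=15.0,
                            offset_mm=[4.0, 3.0, 0.0], noise_sd=0.0, side="left")
    left = make_phantom(left_spec, rng=0)
    # mirror the left phantom's patient space through the sagittal midplane (x -> -x)
    M = np.diag([-1.0, 1.0, 1.0])
    mirrored_mask = SegmentationMask(voxels=left.mask.voxels.copy(),
                                     spacing=left.mask.spacing.copy(),
                                     origin=M @ left.mask.origin,
                                     direction=M @ left.mask.direction)
    mirrored_lm = ScapularLandmarks(M @ left.landmarks.angulus_inferior,
                                    M @ left.landmarks.trigonum_scapulae,
                                    M @ left.landmarks.glenoid_center, side="left")
    qv_l = quadrant_volumes(mirrored_mask, build_frame(mirrored_lm))
    qv_r = quadrant_volumes(right.mask, right.frame)
    for attr in ("total", "aiq", "asq", "psq", "piq"):
        assert getattr(qv_l, attr) == pytest.approx(getattr(qv_r, attr), rel=0.01)


def test_quadrant_label_map_consistent_with_volumes(sphere_phantom):
    ph = sphere_phantom
    labels = quadrant_label_map(ph.mask, ph.frame)
    qv = quadrant_volumes(ph.mask, ph.frame)
    vv = ph.mask.voxel_volume_mm3 / 1000
    counts = np.bincount(labels.voxels.ravel(), minlength=5)
    assert counts[1] * vv == pytest.approx(qv.aiq)
    assert counts[2] * vv == pytest.approx(qv.asq)
    assert counts[3] * vv == pytest.approx(qv.psq)
    assert counts[4] * vv == pytest.approx(qv.piq)
    assert counts[1:].sum() == ph.mask.n_labeled
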