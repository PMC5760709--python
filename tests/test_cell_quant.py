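"""Nucleus/membrane/intracellular segmentation and per-cell fractions."""

from dataclasses import replace

import numpy as np
import pytest

import memphys as m
from memphys.synthetic import simulate_cell_field
from conftest import paint_disk_pools


def disk_image(shape, centers, r, amp=200.0, noise_sd=3.0, seed=0):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.zeros(shape)
    for cy, cx in centers:
        img += amp * (np.hypot(yy - cy, xx - cx) <= r)
    return img + 20.0 + rng.normal(0, noise_sd, shape)


# ------------------------------------------------------------------- nuclei


def test_blank_image_yields_no_nuclei():
    assert m.detect_nuclei(np.zeros((64, 64))).max() == 0
    rng = np.random.default_rng(0)
    labels = m.detect_nuclei(np.full((64, 64), 20.0) + rng.normal(0, 0.5, (64, 64)))
    assert labels.max() <= 1  # pure noise must not fragment into many objects


def test_ten_separated_disks_detected_with_centroids():
    centers = [(30 + 40 * (i // 5), 30 + 40 * (i % 5)) for i in range(10)]
    img = disk_image((110, 220), centers, r=10)
    labels = m.detect_nuclei(img)
    assert labels.max() == 10
    from skimage.measure import regionprops

    found = sorted(tuple(np.round(p.centroid)) for p in regionprops(labels))
    for (fy, fx), (cy, cx) in zip(found, sorted(centers)):
        assert abs(fy - cy) <= 1 and abs(fx - cx) <= 1


def test_overlapping_disks_split_into_two():
    # ~20% area overlap at distance 1.4 r
    img = disk_image((80, 80), [(40, 33), (40, 47)], r=10)
    labels = m.detect_nuclei(img)
    assert len(np.unique(labels)) - 1 == 2


def test_degenerate_params_rejected():
    with pytest.raises(ValueError):
        m.detect_nuclei(np.zeros((32, 32)), smoothing=-1)
    with pytest.raises(ValueError):
        m.detect_nuclei(np.zeros((32, 32)), h=-5)


# ----------------------------------------------------------------- watershed


def test_single_cell_masks_match_truth(control):
    p = replace(control, endo=replace(control.endo, n_cells=1))
    img, truth = simulate_cell_field(p, seed=2)
    nuclei = m.detect_nuclei(img.dapi)
    seg = m.segment_cells(img.membrane, nuclei, thicken_px=5)
    assert len(seg.cell_ids) == 1
    for det, tru in (
        (seg.membrane_mask, truth.membrane_labels > 0),
        (seg.intracellular_mask, truth.interior_labels > 0),
    ):
        iou = (det & tru).sum() / (det | tru).sum()
        assert iou >= 0.9


def test_adjacent_cells_separated_and_disjoint():
    # two touching cells sharing a membrane ridge
    shape = (120, 200)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mem = np.zeros(shape)
    nucimg = np.zeros(shape)
    for cx in (70, 130):
        dist = np.hypot(yy - 60, xx - cx)
        mem += 200.0 * np.exp(-((dist - 30.0) ** 2) / 8.0)
        nucimg += 200.0 * (dist <= 10)
    rng = np.random.default_rng(1)
    mem += 20 + rng.normal(0, 3, shape)
    nuclei = m.detect_nuclei(nucimg + 20 + rng.normal(0, 3, shape))
    assert nuclei.max() == 2
    seg = m.segment_cells(mem, nuclei)
    assert len(seg.cell_ids) == 2
    a, b = seg.cell_ids
    assert not ((seg.cell_labels == a) & (seg.cell_labels == b)).any()
    assert not (seg.membrane_mask & seg.intracellular_mask).any()


def test_thicken_zero_and_no_seeds_rejected(control_cell_field):
    img, _ = control_cell_field
    nuclei = m.detect_nuclei(img.dapi)
    with pytest.raises(ValueError, match="thicken_px"):
        m.segment_cells(img.membrane, nuclei, thicken_px=0)
    with pytest.raises(ValueError, match="seeds"):
        m.segment_cells(img.membrane, np.zeros_like(nuclei))


def test_segmentation_is_deterministic(control_cell_field):
    img, _ = control_cell_field
    n1 = m.detect_nuclei(img.dapi)
    n2 = m.detect_nuclei(img.dapi)
    assert np.array_equal(n1, n2)
    s1 = m.segment_cells(img.membrane, n1)
    s2 = m.segment_cells(img.membrane, n2)
    assert np.array_equal(s1.cell_labels, s2.cell_labels)
    assert np.array_equal(s1.membrane_labels, s2.membrane_labels)


# ----------------------------------------------------------------- fractions


def test_all_membrane_ligand_gives_zero_fraction(control_cell_field, control_segmentation):
    img, truth = control_cell_field
    lig = paint_disk_pools(img.dapi.shape, truth.centers, truth.radii, [(-4.0, -1.0, 1.0)])
    fr = m.endocytosed_fraction(lig, control_segmentation, background=0.0)
    assert fr.mean_fraction == pytest.approx(0.0, abs=1e-9)


def test_all_interior_ligand_gives_unit_fraction(control_cell_field, control_segmentation):
    img, truth = control_cell_field
    lig = paint_disk_pools(img.dapi.shape, truth.centers, truth.radii, [(0.0, -7.0, 1.0)])
    fr = m.endocytosed_fraction(lig, control_segmentation, background=0.0)
    assert fr.mean_fraction == pytest.approx(1.0, abs=1e-9)


def test_intensity_conservation(control_cell_field, control_segmentation):
    """Membrane + intracellular intensity equals the whole-cell intensity."""
    img, _ = control_cell_field
    seg = control_segmentation
    from scipy import ndimage as ndi

    lig = np.clip(img.ligand - 20.0, 0, None)
    mem = ndi.sum_labels(lig, seg.membrane_labels, seg.cell_ids)
    inside = ndi.sum_labels(lig, seg.intracellular_labels, seg.cell_ids)
    total = ndi.sum_labels(lig, seg.cell_labels, seg.cell_ids)
    assert np.allclose(mem + inside, total)


def test_fractions_invariant_to_global_scaling(control_cell_field, control_segmentation):
    img, _ = control_cell_field
    f1 = m.endocytosed_fraction(img.ligand, control_segmentation, background=20.0)
    f2 = m.endocytosed_fraction(5.0 * img.ligand, control_segmentation, background=100.0)
    assert np.allclose(f1.table["fraction"], f2.table["fraction"])


def test_endocytosis_recovery_across_fractions(control):
    """Recovered mean fraction within 0.03 of truth over the f range."""
    for f in (0.1, 0.5, 0.9):
        p = replace(control, endo=replace(control.endo, f_endo=f))
        img, truth = simulate_cell_field(p, seed=10)
        nuclei = m.detect_nuclei(img.dapi)
        seg = m.segment_cells(img.membrane, nuclei)
        fr = m.endocytosed_fraction(img.ligand, seg, background=img.backgrounds[2])
        assert abs(fr.mean_fraction - truth.f_per_cell.mean()) <= 0.03


def test_nuclear_confined_signal_gives_unit_fraction(control_cell_field, control_segmentation):
    img, truth = control_cell_field
    sig = paint_disk_pools(img.dapi.shape, truth.centers, truth.radii, [(0.0, 7.0, 1.0)])
    fr = m.nuclear_fraction(sig, control_segmentation, background=0.0)
    assert fr.mean_fraction == pytest.approx(1.0, abs=1e-6)


def test_uniform_signal_gives_area_ratio(control_segmentation):
    seg = control_segmentation
    sig = np.ones(seg.cell_labels.shape)
    fr = m.nuclear_fraction(sig, seg, background=0.0)
    for row in fr.table.itertuples():
        cid = row.cell_id
        ratio = (seg.nucleus_labels == cid).sum() / (seg.cell_labels == cid).sum()
        assert row.fraction == pytest.approx(ratio, abs=1e-9)


def test_known_nuclear_share_recovered(control_cell_field, control_segmentation):
    """A field built with 70% nuclear signal reads back 0.70 +/- 0.02."""
    img, truth = control_cell_field
    rng = np.random.default_rng(3)
    nucleus_r = 10
    sig = paint_disk_pools(
        img.dapi.shape,
        truth.centers,
        truth.radii,
        [(0.0, nucleus_r - 3.0, 0.7), (nucleus_r + 3.0, -7.0, 0.3)],
    )
    sig += 20.0 + rng.normal(0, 3, sig.shape)
    fr = m.nuclear_fraction(sig, control_segmentation, background=20.0)
    assert fr.mean_fraction == pytest.approx(0.70, abs=0.02)
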