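"""Quantification correctness against constructed inputs and generator truth."""

import numpy as np
import pandas as pd
import pytest

from damagerates import (
    SyntheticImageSpec,
    count_tifs,
    detect_foci_3d,
    measure_cell_telomere_fluorescence,
    measure_pan_nuclear_intensity,
    quantify_stack_3d,
    render_field_2d,
    render_stack_3d,
    segment_nuclei,
)
from damagerates.imaging import FocusSpot, NucleusRegion


def _disk_image(centers, radius=20, value=1000.0, shape=(128, 128)):
    img = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    return img


class TestSegmentation:
    def test_two_disjoint_disks_give_two_regions(self):
        img = _disk_image([(40, 40), (90, 90)])
        regions = segment_nuclei(img, min_area=50)
        assert [r.label for r in regions] == [1, 2]
        assert sum(r.area for r in regions) == pytest.approx(2 * np.pi * 400, rel=0.05)

    def test_border_clipped_disk_excluded(self):
        img = _disk_image([(64, 64), (0, 100)])
        inside_only = segment_nuclei(img, min_area=50, exclude_border=True)
        assert len(inside_only) == 1
        assert not inside_only[0].touches_border
        both = segment_nuclei(img, min_area=50, exclude_border=False)
        assert len(both) == 2

    def test_blank_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="blank"):
            assert segment_nuclei(np.zeros((32, 32))) == []

    def test_synthetic_field_ground_truth_recovery(self):
        spec = SyntheticImageSpec(
            field_shape=(900, 900), n_nuclei=50, psf_sigma=1.0, shot_noise=True,
            nucleus_axes=((7.0, 10.0), (6.0, 8.0)), seed=7,
        )
        image, labels = render_field_2d(spec, np.full(50, 200.0))
        regions = segment_nuclei(image[0], min_area=30)
        detected = np.zeros(image[0].shape, dtype=int)
        for r in regions:
            detected[tuple(r.coords.T)] = r.label
        hits = 0
        for lab in range(1, 51):
            cy, cx = np.argwhere(labels == lab).mean(axis=0).round().astype(int)
            if detected[cy, cx] > 0:
                hits += 1
        assert hits >= 48


class TestPanNuclearIntensity:
    def test_single_pixel_region_returns_its_value(self):
        region = NucleusRegion(
            label=1, coords=np.array([[3, 4]]), centroid=(3.0, 4.0),
            area=1, touches_border=False, image_shape=(8, 8),
        )
        img = np.zeros((8, 8))
        img[3, 4] = 42.5
        assert measure_pan_nuclear_intensity([region], img)[0] == 42.5

    def test_noiseless_field_measures_assigned_plus_background(self):
        spec = SyntheticImageSpec(
            field_shape=(620, 620), n_nuclei=20, psf_sigma=0.0, shot_noise=False,
            background_level=10.0, seed=13,
        )
        assigned = np.linspace(100, 800, 20)
        image, labels = render_field_2d(spec, assigned)
        regions = segment_nuclei(image[0], min_area=30)
        assert len(regions) == 20
        means = measure_pan_nuclear_intensity(regions, image[1])
        # match detected regions to ground-truth nuclei via the label map
        for r, mean in zip(regions, means):
            gt_label = labels[tuple(np.asarray(r.coords[len(r.coords) // 2]))]
            assert abs(mean - (assigned[gt_label - 1] + 10.0)) < 0.5

    def test_shape_mismatch_rejected(self):
        region = NucleusRegion(
            label=1, coords=np.array([[0, 0]]), centroid=(0.0, 0.0),
            area=1, touches_border=True, image_shape=(8, 8),
        )
        with pytest.raises(ValueError):
            measure_pan_nuclear_intensity([region], np.zeros((4, 4)))


STACK_KW = dict(
    field_shape=(28, 180, 180),
    n_nuclei=6,
    nucleus_axes=((7.0, 9.0), (13.0, 17.0), (13.0, 17.0)),
    psf_sigma=0.0,
    shot_noise=False,
    background_level=0.0,
)


@pytest.fixture(scope="module")
def stack_with_truth():
    spec = SyntheticImageSpec(tif_pairs=3, edge_spots=2, seed=11, **STACK_KW)
    stack, labels, foci = render_stack_3d(spec)
    regions = segment_nuclei(stack[0], min_area=200)
    return stack, labels, foci, regions


class TestFociDetection:
    def test_spots_found_at_ground_truth_centroids(self, stack_with_truth):
        stack, labels, foci, regions = stack_with_truth
        spots = detect_foci_3d(stack[1], regions, min_spot_intensity=100.0)
        truth = [f for f in foci if f["channel"] == "telomere"]
        assert len(spots) == len(truth)
        gt = np.array([f["centroid"] for f in truth])
        for s in spots:
            assert np.linalg.norm(gt - np.asarray(s.centroid), axis=1).min() <= 1.0

    def test_uniform_channel_yields_no_spots(self, stack_with_truth):
        stack, _, _, regions = stack_with_truth
        flat = np.zeros_like(stack[1])
        assert detect_foci_3d(flat, regions, min_spot_intensity=100.0) == []

    def test_rim_spot_flagged(self, stack_with_truth):
        stack, _, foci, regions = stack_with_truth
        spots = detect_foci_3d(stack[2], regions, min_spot_intensity=100.0, rim_margin=3.0)
        n_rim_truth = sum(f["near_rim"] for f in foci)
        assert sum(s.near_rim for s in spots) == n_rim_truth > 0

    def test_2d_input_rejected(self, stack_with_truth):
        _, _, _, regions = stack_with_truth
        with pytest.raises(ValueError):
            detect_foci_3d(np.zeros((16, 16)), regions, min_spot_intensity=1.0)


def _spot(channel, nucleus, centroid, near_rim=False, intensity=100.0):
    return FocusSpot(channel=channel, centroid=centroid, intensity=intensity,
                     nucleus=nucleus, near_rim=near_rim)


class TestTifCounting:
    def test_constructed_pairs_fraction(self):
        tel = [_spot("telomere", n, (5.0, 5.0, 5.0)) for n in range(1, 5)]
        bp1 = [_spot("53bp1", n, (5.0, 5.0, 5.0)) for n in range(1, 5)]
        out = count_tifs(tel, bp1, max_distance=2.0, nucleus_labels=list(range(1, 11)))
        assert out.pct_cells_with_tif == 40.0
        assert out.n_pairs == 4

    def test_rim_spots_never_counted(self):
        tel = [_spot("telomere", 1, (5.0, 5.0, 5.0))]
        bp1 = [_spot("53bp1", 1, (5.0, 5.0, 5.0), near_rim=True)]
        out = count_tifs(tel, bp1, nucleus_labels=[1, 2])
        assert out.pct_cells_with_tif == 0.0
        assert out.n_pairs == 0

    def test_permutation_invariance_and_pair_bound(self, rng):
        tel = [_spot("telomere", 1, tuple(c)) for c in rng.uniform(0, 20, (5, 3))]
        bp1 = [_spot("53bp1", 1, tuple(c)) for c in rng.uniform(0, 20, (3, 3))]
        base = count_tifs(tel, bp1, max_distance=8.0, nucleus_labels=[1])
        for _ in range(5):
            t2 = [tel[i] for i in rng.permutation(5)]
            b2 = [bp1[i] for i in rng.permutation(3)]
            again = count_tifs(t2, b2, max_distance=8.0, nucleus_labels=[1])
            assert again.per_nucleus == base.per_nucleus
        assert base.per_nucleus[1] <= min(len(tel), len(bp1))

    def test_pct_monotone_in_max_distance(self, rng):
        tel = [_spot("telomere", n % 4 + 1, tuple(c)) for n, c in enumerate(rng.uniform(0, 30, (12, 3)))]
        bp1 = [_spot("53bp1", n % 4 + 1, tuple(c)) for n, c in enumerate(rng.uniform(0, 30, (12, 3)))]
        pcts = [
            count_tifs(tel, bp1, max_distance=d, nucleus_labels=[1, 2, 3, 4]).pct_cells_with_tif
            for d in (0.5, 1, 2, 4, 8, 16, 60)
        ]
        assert pcts == sorted(pcts)

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            count_tifs([], [], max_distance=0.0)

    def test_synthetic_stack_recovers_exactly_k_pairs(self, stack_with_truth):
        stack, _, foci, regions = stack_with_truth
        tel = detect_foci_3d(stack[1], regions, 100.0, channel_name="telomere")
        bp1 = detect_foci_3d(stack[2], regions, 100.0, channel_name="53bp1")
        out = count_tifs(tel, bp1, max_distance=2.0, nucleus_labels=[r.label for r in regions])
        assert out.n_pairs == 3


class TestTelomereFluorescence:
    def test_sum_of_spot_intensities(self):
        spots = [
            _spot("telomere", 1, (0.0, 0.0, 0.0), intensity=10),
            _spot("telomere", 1, (9.0, 0.0, 0.0), intensity=20),
            _spot("telomere", 1, (0.0, 9.0, 0.0), intensity=30),
        ]
        out = measure_cell_telomere_fluorescence(spots, nucleus_labels=[1, 2])
        assert out.loc[out.nucleus == 1, "telomere_fluorescence"].item() == 60.0
        row2 = out[out.nucleus == 2].iloc[0]
        assert row2["telomere_fluorescence"] == 0.0 and bool(row2["no_spots"])

    def test_noiseless_stack_sums_match_injected_totals(self, stack_with_truth):
        stack, _, foci, regions = stack_with_truth
        tel = detect_foci_3d(stack[1], regions, 100.0)
        table = measure_cell_telomere_fluorescence(tel, nucleus_labels=[r.label for r in regions])
        truth = {}
        for f in foci:
            if f["channel"] == "telomere":
                truth[f["nucleus"]] = truth.get(f["nucleus"], 0.0) + f["intensity"]
        for _, row in table.iterrows():
            assert row["telomere_fluorescence"] == pytest.approx(truth[row["nucleus"]], rel=0.02)


def test_quantify_stack_3d_end_to_end(stack_with_truth):
    stack, _, foci, _ = stack_with_truth
    table, tifs = quantify_stack_3d(stack, min_spot_intensity=100.0)
    assert len(table) == 6
    assert tifs.n_pairs == 3
    assert (table["n_tifs"] <= np.minimum(table["n_telomere_spots"], table["n_53bp1_foci"])).all()
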