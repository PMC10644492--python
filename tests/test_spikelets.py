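"""Spikelet detection: morphology, EDT, markers, watershed, ellipse fits."""
import numpy as np
import pytest
from scipy import ndimage as ndi

from spykit import synth
from spykit.errors import DegenerateInputError, ValidationError
from spykit.spikelets import (SpikeletParams, distance_map, find_markers,
                              fit_spikelet_ellipses, min_distance_sweep,
                              preprocess_mask, spikelet_segm, watershed_split)

from _oracles import edt_brute_force
from conftest import disk_mask, rectangle_mask


def two_disk_mask(sep=60, radius=20, pad=10):
    h = 2 * (radius + pad)
    w = sep + 2 * (radius + pad)
    yy, xx = np.mgrid[:h, :w]
    c1 = (h // 2, radius + pad)
    c2 = (h // 2, radius + pad + sep)
    m = ((yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 <= radius ** 2) | \
        ((yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 <= radius ** 2)
    return m, c1, c2


class TestPreprocess:
    def test_identity_configuration(self):
        mask = rectangle_mask(30, 60)
        params = SpikeletParams(morph_rescale=1.0, erosion_iter=0,
                                opening_iter=0)
        assert np.array_equal(preprocess_mask(mask, params), mask)

    def test_boundary_retreat_is_bounded(self):
        mask = rectangle_mask(120, 200, pad=20)
        cleaned = preprocess_mask(mask, SpikeletParams())
        assert cleaned.any()
        assert not (cleaned & ~mask).any()          # never grows
        # retreat limited to about (1/morph_rescale) cells around the rim
        eroded_band = mask & ~ndi.binary_erosion(mask, iterations=25)
        assert (mask & ~cleaned & ~eroded_band).sum() == 0

    def test_thin_mask_vanishes(self):
        mask = rectangle_mask(3, 100)
        with pytest.raises(DegenerateInputError):
            preprocess_mask(mask, SpikeletParams())

    def test_empty_mask(self):
        with pytest.raises(DegenerateInputError):
            preprocess_mask(np.zeros((10, 10), dtype=bool), SpikeletParams())


class TestDistanceMap:
    def test_disk_peak_at_center(self):
        mask = disk_mask(25)
        d = distance_map(mask)
        assert d.max() == pytest.approx(25, abs=1.5)
        assert d[~mask].max() == 0.0

    def test_single_pixel(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        assert distance_map(mask)[3, 3] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_small_rasters(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((40, 45)) < 0.4
        assert np.allclose(distance_map(mask), edt_brute_force(mask))


class TestMarkers:
    def test_two_disks_two_markers(self):
        mask, c1, c2 = two_disk_mask(sep=60, radius=20)
        markers = find_markers(distance_map(mask), min_distance=25)
        assert len(markers) == 2
        found = {tuple(m) for m in markers}
        for c in (c1, c2):
            assert min(np.hypot(m[0] - c[0], m[1] - c[1]) for m in found) < 3

    def test_large_min_distance_suppresses(self):
        mask, *_ = two_disk_mask(sep=60, radius=20)
        markers = find_markers(distance_map(mask), min_distance=70)
        assert len(markers) == 1

    def test_flat_zero_map(self):
        assert len(find_markers(np.zeros((10, 10)), 25)) == 0

    def test_pairwise_separation_and_monotonicity(self, straight_spike):
        from spykit.benchmarks import RECOVERY_PARAMS

        cleaned = preprocess_mask(straight_spike["mask"], RECOVERY_PARAMS)
        d = distance_map(cleaned)
        counts = []
        for md in (5, 15, 25, 40, 60, 90):
            markers = find_markers(d, md)
            counts.append(len(markers))
            if len(markers) > 1:
                diffs = markers[:, None, :] - markers[None, :, :]
                dist = np.sqrt((diffs ** 2).sum(-1))
                np.fill_diagonal(dist, np.inf)
                assert dist.min() >= md
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestWatershed:
    def test_partition_and_conservation(self):
        mask, c1, c2 = two_disk_mask(sep=36, radius=20)  # touching dumbbell
        d = distance_map(mask)
        markers = find_markers(d, min_distance=25)
        labels = watershed_split(d, markers, mask)
        assert set(np.unique(labels[mask])) == {1, 2}
        assert (labels[~mask] == 0).all()
        assert (labels[mask] > 0).all()
        assert (labels > 0).sum() == mask.sum()

    def test_symmetric_split_boundary(self):
        mask, c1, c2 = two_disk_mask(sep=36, radius=20)
        d = distance_map(mask)
        markers = find_markers(d, min_distance=25)
        labels = watershed_split(d, markers, mask)
        mid = (c1[1] + c2[1]) / 2
        border = (labels == 1) & (
            ndi.binary_dilation(labels == 2, np.ones((3, 3))))
        cols = np.nonzero(border)[1]
        assert np.all(np.abs(cols - mid) <= 2)

    def test_single_and_zero_markers(self):
        mask = disk_mask(15)
        d = distance_map(mask)
        one = watershed_split(d, np.array([[20, 20]]), mask)
        assert (one[mask] == 1).all()
        zero = watershed_split(d, np.zeros((0, 2)), mask)
        assert not zero.any()

    def test_marker_outside_mask_rejected(self):
        mask = disk_mask(10)
        with pytest.raises(ValidationError):
            watershed_split(distance_map(mask), np.array([[0, 0]]), mask)


class TestEllipseFits:
    def test_axis_aligned_angle(self):
        mask = np.zeros((60, 120), dtype=bool)
        yy, xx = np.mgrid[:60, :120]
        mask |= ((xx - 60) / 40) ** 2 + ((yy - 30) / 15) ** 2 <= 1
        rec = fit_spikelet_ellipses(mask.astype(int))[0]
        assert rec.angle == pytest.approx(0.0, abs=2.0)
        assert rec.area == pytest.approx(np.pi * 40 * 15, rel=0.03)
        assert rec.major_axis_length == pytest.approx(80, rel=0.05)

    @pytest.mark.parametrize("angle", [30.0, 45.0, 120.0])
    def test_rotated_angle_recovered(self, angle):
        canvas = np.zeros((160, 160), dtype=bool)
        synth._fill_rotated_ellipse(canvas, (80, 80), 45, 16,
                                    np.radians(angle))
        rec = fit_spikelet_ellipses(canvas.astype(int))[0]
        assert rec.angle == pytest.approx(angle % 180.0, abs=2.0)
        assert 0 <= rec.angle < 180

    def test_tiny_region_flagged_degenerate(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[4, 4:6] = 1
        rec = fit_spikelet_ellipses(labels)[0]
        assert rec.degenerate and np.isnan(rec.angle)


class TestSpikeletSegm:
    def test_recovers_known_count(self):
        from spykit.benchmarks import RECOVERY_PARAMS

        spec = synth.SpikeSpec(arc_length=550.0, n_spikelets=10,
                               spikelet_spacing=50.0)
        mask, _, truth = synth.render_spike(spec, seed=2)
        result = spikelet_segm(mask, RECOVERY_PARAMS)
        assert abs(result.count - truth.spikelet_count) <= 1

    def test_rachis_only_spike_yields_at_most_one(self):
        spec = synth.SpikeSpec(arc_length=400.0, n_spikelets=0,
                               rachis_width=12.0)
        mask, _, _ = synth.render_spike(spec, seed=2)
        result = spikelet_segm(mask, SpikeletParams())
        assert result.count <= 1

    def test_area_filter_removes_speck(self):
        mask, *_ = two_disk_mask(sep=80, radius=20)
        mask[2, 2] = True  # isolated speck survives identity preprocessing
        params = SpikeletParams(morph_rescale=1.0, erosion_iter=0,
                                opening_iter=0, min_distance=10,
                                area_filter=(50, 5000))
        result = spikelet_segm(mask, params)
        assert result.count == 2
        assert all(50 <= r.area <= 5000 for r in result.records)

    def test_annotation_shape(self, straight_spike):
        from spykit.benchmarks import RECOVERY_PARAMS

        result = spikelet_segm(straight_spike["mask"], RECOVERY_PARAMS,
                               annotate=True)
        assert result.annotated.shape == straight_spike["mask"].shape + (3,)


class TestSweep:
    def test_rmse_rises_past_spacing(self):
        from spykit.benchmarks import RECOVERY_PARAMS

        rng = np.random.default_rng(3)
        masks, counts = [], []
        for _ in range(4):
            n = int(rng.integers(8, 12))
            spec = synth.SpikeSpec(arc_length=(n + 0.5) * 55.0,
                                   n_spikelets=n, spikelet_spacing=55.0,
                                   orientation=90.0)
            mask, _, truth = synth.render_spike(
                spec, seed=int(rng.integers(0, 2 ** 31 - 1)))
            masks.append(mask)
            counts.append(truth.spikelet_count)
        table = min_distance_sweep(masks, counts, [25, 45, 80],
                                   RECOVERY_PARAMS)
        assert list(table.columns) == ["min_distance", "rmse", "sd"]
        assert table.rmse.iloc[0] <= 1.0
        assert table.rmse.iloc[-1] > table.rmse.iloc[0]

    def test_empty_range_rejected(self, straight_spike):
        with pytest.raises(ValidationError):
            min_distance_sweep([straight_spike["mask"]], [10], [])
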