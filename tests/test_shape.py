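"""Shape descriptors: geometric battery and elliptical Fourier analysis."""
import numpy as np
import pytest

from spykit.errors import DegenerateInputError, ValidationError
from spykit.shape import (efd_coefficients, efd_symmetry_split,
                          extract_contour, fourier_power,
                          harmonics_for_power, normalize_efd,
                          reconstruct_contour, reconstruction_error,
                          region_geometry)

from _oracles import (efd_brute_force, ellipse_contour, fourier_blob_contour,
                      star_contour)
from conftest import disk_mask, rectangle_mask


class TestGeometry:
    def test_square_closed_forms(self):
        g = region_geometry(rectangle_mask(100, 100))
        assert g.extent == pytest.approx(1.0, abs=0.01)
        assert g.solidity == pytest.approx(1.0, abs=0.02)
        assert g.eccentricity == pytest.approx(0.0, abs=0.05)
        assert g.feret_max == pytest.approx(100 * np.sqrt(2), rel=0.02)
        assert g.feret_min == pytest.approx(100, rel=0.02)
        assert g.perimeter == pytest.approx(400, rel=0.02)
        assert g.equivalent_diameter == pytest.approx(
            np.sqrt(4 * g.area / np.pi))

    def test_disk_closed_forms(self):
        g = region_geometry(disk_mask(50))
        assert g.area == pytest.approx(np.pi * 50 ** 2, rel=0.02)
        assert g.equivalent_diameter == pytest.approx(100, rel=0.02)
        assert g.solidity > 0.98
        assert g.perimeter == pytest.approx(2 * np.pi * 50, rel=0.05)
        assert g.major_axis == pytest.approx(g.minor_axis, rel=0.02)

    def test_thin_line_degenerate_geometry(self):
        mask = np.zeros((10, 200), dtype=bool)
        mask[5, 5:195] = True
        g = region_geometry(mask)
        assert g.feret_min <= 1.5
        assert g.minor_axis <= g.major_axis
        assert g.feret_min <= g.feret_max

    def test_rectangle_invariants(self):
        g = region_geometry(rectangle_mask(40, 160))
        assert g.minor_axis <= g.major_axis
        assert g.feret_min <= g.feret_max
        assert 0 < g.extent <= 1
        assert 0 < g.solidity <= 1.001

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            region_geometry(np.zeros((5, 5), dtype=bool))


class TestContour:
    def test_hole_is_filled(self):
        mask = rectangle_mask(60, 60)
        holey = mask.copy()
        holey[25:40, 25:40] = False
        c1 = extract_contour(mask)
        c2 = extract_contour(holey)
        assert np.allclose(c1, c2)

    def test_square_contour_length(self):
        from spykit.shape import contour_perimeter

        c = extract_contour(rectangle_mask(80, 80))
        assert contour_perimeter(c) == pytest.approx(4 * 80, rel=0.02)

    def test_disk_contour_length(self):
        from spykit.shape import contour_perimeter

        c = extract_contour(disk_mask(40))
        assert contour_perimeter(c) == pytest.approx(2 * np.pi * 40, rel=0.05)

    def test_counter_clockwise_and_closed(self, straight_spike):
        c = extract_contour(straight_spike["mask"])
        assert np.allclose(c[0], c[-1])
        x, y = c[:, 0], c[:, 1]
        area = 0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
        assert area > 0

    def test_tiny_mask_rejected(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        with pytest.raises(DegenerateInputError):
            extract_contour(m)


def fixture_contours():
    return [
        ellipse_contour(60, 25),
        ellipse_contour(40, 40, cx=10, cy=-5),
        star_contour(),
        fourier_blob_contour(seed=3),
        fourier_blob_contour(seed=8),
    ]


class TestEFD:
    @pytest.mark.parametrize("idx", range(5))
    def test_coefficients_match_integration_oracle(self, idx):
        contour = fixture_contours()[idx]
        efd = efd_coefficients(contour, 30)
        coeffs, a0, c0 = efd_brute_force(contour, 30)
        scale = max(1.0, np.abs(coeffs).max())
        assert np.abs(efd.coeffs - coeffs).max() < 1e-6 * scale
        assert efd.a0 == pytest.approx(a0, abs=1e-6 * scale)
        assert efd.c0 == pytest.approx(c0, abs=1e-6 * scale)

    def test_ellipse_power_concentrates_in_first_harmonic(self):
        # an eccentric ellipse under chord-length parameterization leaks a
        # little power upward; a circle is exactly single-harmonic
        efd = efd_coefficients(ellipse_contour(60, 25), 20)
        power = 0.5 * (efd.coeffs ** 2).sum(axis=1)
        assert power[0] / power.sum() > 0.99
        efd = efd_coefficients(ellipse_contour(40, 40), 20)
        power = 0.5 * (efd.coeffs ** 2).sum(axis=1)
        assert power[0] / power.sum() > 0.9999999

    def test_translation_moves_only_offsets(self):
        c = fourier_blob_contour(seed=3)
        e1 = efd_coefficients(c, 15)
        e2 = efd_coefficients(c + [37.0, -12.5], 15)
        assert np.allclose(e1.coeffs, e2.coeffs, atol=1e-9)
        assert e2.a0 - e1.a0 == pytest.approx(37.0, abs=1e-9)
        assert e2.c0 - e1.c0 == pytest.approx(-12.5, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            efd_coefficients(ellipse_contour(10, 5), 0)
        with pytest.raises(ValidationError):
            efd_coefficients(np.zeros((2, 2)), 5)


class TestNormalization:
    def test_rotation_scale_invariance(self):
        c = fourier_blob_contour(seed=3)
        phi = np.radians(37.0)
        rot = np.array([[np.cos(phi), -np.sin(phi)],
                        [np.sin(phi), np.cos(phi)]])
        c2 = 2.3 * (c @ rot.T)
        n1 = normalize_efd(efd_coefficients(c, 20))
        n2 = normalize_efd(efd_coefficients(c2, 20))
        assert np.abs(n1.coeffs - n2.coeffs).max() < 1e-6

    def test_idempotent(self):
        n1 = normalize_efd(efd_coefficients(star_contour(), 12))
        n2 = normalize_efd(n1)
        assert np.allclose(n1.coeffs, n2.coeffs, atol=1e-9)

    def test_circle_canonical_form(self):
        n = normalize_efd(efd_coefficients(ellipse_contour(40, 40), 10))
        first = n.coeffs[0].reshape(2, 2)
        assert abs(first[0, 0] - 1.0) < 1e-3
        assert abs(abs(first[1, 1]) - 1.0) < 1e-3
        assert abs(first[0, 1]) < 1e-3 and abs(first[1, 0]) < 1e-3
        assert np.abs(n.coeffs[1:]).max() < 1e-3


class TestFourierPower:
    def test_cumulative_power_monotone_to_one(self):
        efd = efd_coefficients(star_contour(), 40)
        frac = fourier_power(efd)
        assert np.all(np.diff(frac) >= -1e-12)
        assert frac[-1] == pytest.approx(1.0)

    def test_circular_ellipse_needs_one_harmonic(self):
        assert harmonics_for_power(ellipse_contour(40, 40), 0.9999) == 1
        # eccentricity leaks a little power into odd harmonics
        assert harmonics_for_power(ellipse_contour(60, 25), 0.9999) <= 5

    def test_square_matches_oracle_power(self):
        c = extract_contour(rectangle_mask(60, 60))
        n_star = harmonics_for_power(c, 0.99, max_harmonics=60)
        coeffs, _, _ = efd_brute_force(c, 60)
        power = 0.5 * (coeffs ** 2).sum(axis=1)
        frac = np.cumsum(power) / power.sum()
        assert n_star == int(np.nonzero(frac > 0.99)[0][0]) + 1

    def test_threshold_monotonicity(self):
        c = fourier_blob_contour(seed=8)
        assert harmonics_for_power(c, 0.5) <= harmonics_for_power(c, 0.9999)

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            harmonics_for_power(star_contour(), 1.5)


class TestReconstruction:
    def test_ellipse_reconstructs_exactly(self):
        c = ellipse_contour(60, 25)
        assert reconstruction_error(c, 10) < 0.5

    def test_error_non_increasing_in_harmonics(self, straight_spike):
        c = extract_contour(straight_spike["mask"])
        errs = [reconstruction_error(c, n) for n in (1, 10, 30)]
        assert errs[0] >= errs[1] >= errs[2]

    def test_first_harmonic_is_an_ellipse(self):
        c = star_contour()
        efd = efd_coefficients(c, 10)
        locus = reconstruct_contour(efd, 1, n_points=200)
        # a 1-harmonic locus carries all its power in harmonic 1
        refd = efd_coefficients(locus, 5)
        power = 0.5 * (refd.coeffs ** 2).sum(axis=1)
        assert power[0] / power.sum() > 0.9999

    def test_harmonic_bounds_validated(self):
        efd = efd_coefficients(star_contour(), 5)
        with pytest.raises(ValidationError):
            reconstruct_contour(efd, 9)


class TestSymmetrySplit:
    def test_power_partition(self):
        efd = normalize_efd(efd_coefficients(fourier_blob_contour(5), 15))
        split = efd_symmetry_split(efd)
        total = 0.5 * (efd.coeffs ** 2).sum()
        assert split["sym_power"] + split["asym_power"] == pytest.approx(total)

    def test_zeroed_symmetric_block(self):
        efd = efd_coefficients(star_contour(), 8)
        efd.coeffs[:, 1] = 0.0
        efd.coeffs[:, 2] = 0.0
        assert efd_symmetry_split(efd)["sym_power"] == 0.0
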