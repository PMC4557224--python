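"""Histograms, intersection distances, gradients and sink detection."""

import numpy as np
import pytest

from histofield import (
    RBFParams,
    ScalarField,
    cluster_points,
    divergence_sinks,
    field_histogram,
    histogram_intersection,
    intersection_distance_profile,
    niche_allocation,
    normalized_gradient,
    point_field,
)
from histofield.errors import DegenerateFieldError, FieldStateError
from .conftest import CENTER, SHAPE, offset_points


def _norm(values):
    return ScalarField(np.asarray(values, float), True, RBFParams.direct(), 1)


class TestFieldHistogram:
    def test_two_spike_field(self):
        vals = np.zeros((10, 10))
        vals[0, 0] = 100.0
        h = field_histogram(_norm(vals), n_bins=100)
        assert h.masses[0] == pytest.approx(99 / 100)
        assert h.masses[-1] == pytest.approx(1 / 100)

    def test_masses_sum_to_one(self, center_field):
        h = field_histogram(center_field, 100)
        assert h.masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_binning_oracle(self, center_field):
        h = field_histogram(center_field, 100)
        vals = center_field.values.ravel()
        for lo in (0, 25, 60, 99):
            hi = lo + 1
            if hi == 100:
                expected = np.sum((vals >= lo) & (vals <= 100)) / vals.size
            else:
                expected = np.sum((vals >= lo) & (vals < hi)) / vals.size
            assert h.masses[lo] == pytest.approx(expected, abs=1e-12)

    def test_unnormalized_field_rejected(self):
        raw = point_field([CENTER], SHAPE, normalize=False)
        with pytest.raises(FieldStateError):
            field_histogram(raw)


class TestHistogramIntersection:
    def test_identical_fields(self, center_field):
        h = field_histogram(center_field)
        assert histogram_intersection(h, h) == pytest.approx(1.0)

    def test_symmetry_and_range(self, center_field, field_cache):
        h1 = field_histogram(center_field)
        h2 = field_histogram(field_cache(offset_points(100)))
        v12 = histogram_intersection(h1, h2)
        assert v12 == histogram_intersection(h2, h1)
        assert 0.0 <= v12 < 1.0

    def test_bin_mismatch(self, center_field):
        h1 = field_histogram(center_field, 100)
        h2 = field_histogram(center_field, 50)
        with pytest.raises(ValueError):
            histogram_intersection(h1, h2)


class TestIntersectionProfile:
    def test_zero_distance_is_unity(self, direct_params):
        prof = intersection_distance_profile(direct_params, [0])
        assert prof[0][1] == pytest.approx(1.0)

    def test_profile_non_increasing(self, direct_params):
        ds = [10, 40, 80, 120, 160, 200, 240]
        prof = intersection_distance_profile(direct_params, ds)
        vals = [v for _, v in prof]
        assert all(x >= y for x, y in zip(vals, vals[1:])), vals

    def test_out_of_image_distance_rejected(self, direct_params):
        with pytest.raises(ValueError):
            intersection_distance_profile(direct_params, [400])


class TestNormalizedGradient:
    def test_mean_is_one(self, center_field):
        g = normalized_gradient(center_field)
        assert g.mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_at_peak(self, center_field):
        g = np.gradient(center_field.values)
        mag = np.hypot(*g)
        assert mag[CENTER] == pytest.approx(0.0, abs=1e-9)

    def test_matches_analytic_derivative(self):
        """Central differences reproduce the kernel's axial derivative
        to well under 2 % at 20 px from the peak (smooth full-support field)."""
        raw = point_field([CENTER], SHAPE, support="full", normalize=False)
        num = np.gradient(raw.values, axis=1)[CENTER[0], CENTER[1] + 20]
        a, b, g = 100 / np.sqrt(2 / 3), 3.0, 0.01
        dc = 20.0
        inner = 1 / (b + g * dc**2)
        d_inner = -2 * g * dc / (b + g * dc**2) ** 2
        analytic = a * d_inner / (2 * np.sqrt(inner + 1 / b))
        assert num == pytest.approx(analytic, rel=0.02)

    def test_constant_field_error(self):
        with pytest.raises(DegenerateFieldError):
            normalized_gradient(_norm(np.full((5, 5), 3.0)))


class TestDivergenceSinks:
    def test_single_point_single_sink(self, field_cache):
        f = field_cache([CENTER], kernel_shape="radial", support="full")
        report = divergence_sinks(f)
        assert report.n_sinks == 1
        r, c = report.sink_centroids[0]
        assert abs(r - CENTER[0]) < 3 and abs(c - CENTER[1]) < 3

    @pytest.mark.parametrize("spacing,expected", [(10, 1), (25, 1), (125, 5)])
    def test_cluster_fuse_and_split(self, field_cache, spacing, expected):
        pts = cluster_points(CENTER, 5, spacing)
        f = field_cache(pts, kernel_shape="radial", support="full")
        assert divergence_sinks(f).n_sinks == expected

    def test_sink_count_monotone_in_spacing(self, field_cache):
        counts = []
        for s in (10, 25, 50, 75, 100, 125):
            pts = cluster_points(CENTER, 5, s)
            f = field_cache(pts, kernel_shape="radial", support="full")
            counts.append(divergence_sinks(f).n_sinks)
        assert all(1 <= c <= 5 for c in counts)
        assert all(x <= y for x, y in zip(counts, counts[1:])), counts

    def test_divergence_theorem(self, field_cache):
        """The discrete divergence sums to the boundary flux (near zero
        relative to the total absolute divergence)."""
        f = field_cache([CENTER], kernel_shape="radial", support="full")
        gr, gc = np.gradient(f.values)
        div = np.gradient(gr, axis=0) + np.gradient(gc, axis=1)
        boundary_flux = (
            np.abs(gr[0]).sum()
            + np.abs(gr[-1]).sum()
            + np.abs(gc[:, 0]).sum()
            + np.abs(gc[:, -1]).sum()
        )
        assert abs(div.sum()) <= boundary_flux * 1.05 + 1e-9
        assert abs(div.sum()) < 0.2 * np.abs(div).sum()

    def test_constant_field_error(self):
        with pytest.raises(DegenerateFieldError):
            divergence_sinks(_norm(np.full((5, 5), 3.0)))

    def test_bad_threshold(self, field_cache):
        f = field_cache([CENTER], kernel_shape="radial", support="full")
        with pytest.raises(ValueError):
            divergence_sinks(f, rel_threshold=1.5)


@pytest.fixture(scope="module")
def band_setup():
    bone = np.zeros((300, 300))
    bone[140:160, :] = 1
    bone_field = point_field(bone, (300, 300))

    def cell(r, c):
        return point_field([(r, c)], (300, 300))

    return bone_field, cell


class TestNicheAllocation:
    def test_fixed_offset_band_has_tight_sd(self, band_setup):
        bone_field, cell = band_setup
        # cells strung along the band at a fixed 40 px offset, away from corners
        cells = [cell(200, c) for c in range(60, 250, 35)]
        result = niche_allocation(cells, bone_field, intersection_threshold=0.45)
        assert result.sd < 0.1
        assert np.all(result.allocated)

    def test_intersection_monotone_in_distance(self, band_setup):
        bone_field, cell = band_setup
        offsets = [0, 20, 40, 60, 100, 130]
        cells = [cell(min(160 + off, 299), 150) for off in offsets]
        result = niche_allocation(cells, bone_field, intersection_threshold=0.7)
        inter = result.intersections
        assert all(x >= y for x, y in zip(inter, inter[1:])), inter
        # the on-bone cell is allocated, the farthest is not
        assert result.allocated[0] and not result.allocated[-1]

    def test_empty_object_list(self, band_setup):
        bone_field, _ = band_setup
        with pytest.raises(ValueError):
            niche_allocation([], bone_field, 0.5)
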