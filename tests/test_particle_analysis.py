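"""Particle measurement, positive fractions, find-maxima, foci assignment."""

import numpy as np
import pytest

from histopipes.particle_analysis import (
    FociSet,
    analyze_particles,
    assign_foci,
    find_maxima,
    percent_positive,
)


class TestAnalyzeParticles:
    def test_empty_mask(self):
        records, summary = analyze_particles(np.zeros((10, 10), bool))
        assert records == [] and summary.count == 0
        assert summary.total_area == 0 and summary.percent_area == 0

    def test_square_closed_form(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        records, summary = analyze_particles(m, scale=1.0)
        (r,) = records
        assert r.area == 100 and r.perimeter == pytest.approx(40.0)
        assert r.circularity == pytest.approx(4 * np.pi * 100 / 1600)
        assert r.centroid == (9.5, 9.5)
        assert not r.touches_edge

    def test_disc_circularity_high(self, disc_mask):
        records, _ = analyze_particles(disc_mask(20))
        assert 0.90 <= records[0].circularity <= 1.0

    def test_disc_circularity_increases_with_radius(self, disc_mask):
        circs = [analyze_particles(disc_mask(r))[0][0].circularity for r in (5, 10, 20, 40)]
        assert all(a <= b + 1e-9 for a, b in zip(circs, circs[1:]))

    def test_elongated_rectangle_low_circularity(self):
        m = np.zeros((20, 60), bool)
        m[5:15, 5:45] = True  # 4:1
        records, _ = analyze_particles(m)
        assert records[0].circularity < 0.7

    def test_area_conservation_and_scale(self, rng):
        m = rng.random((40, 40)) > 0.6
        records, summary = analyze_particles(m, scale=0.5)
        assert summary.total_area == pytest.approx(m.sum() * 0.25)
        assert sum(r.area for r in records) == pytest.approx(summary.total_area)

    def test_mean_intensity_and_edge_flag(self):
        m = np.zeros((10, 10), bool)
        m[0:3, 0:3] = True
        intensity = np.full((10, 10), 7.0)
        records, summary = analyze_particles(m, intensity=intensity)
        assert records[0].mean_intensity == 7.0
        assert records[0].touches_edge
        assert summary.mean_intensity == 7.0

    def test_intensity_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            analyze_particles(np.zeros((5, 5), bool), intensity=np.zeros((4, 4)))


class TestPercentPositive:
    def _summary(self, area, count=1):
        from histopipes.particle_analysis import ParticleSummary

        return ParticleSummary(count, area, area / max(count, 1), 0.0, None)

    def test_ratios(self):
        out = percent_positive(self._summary(100.0, 4), self._summary(25.0, 1))
        assert out["percent_positive_area"] == pytest.approx(25.0)
        assert out["percent_positive_count"] == pytest.approx(25.0)

    def test_full_and_zero(self):
        total = self._summary(50.0, 2)
        assert percent_positive(total, total)["percent_positive_area"] == 100.0
        assert percent_positive(total, self._summary(0.0, 0))["percent_positive_area"] == 0.0

    def test_zero_total_reported_missing(self):
        out = percent_positive(self._summary(0.0, 0), self._summary(0.0, 0))
        assert out["percent_positive_area"] is None
        assert out["percent_positive_count"] is None


def _peaks_image(centers, amplitude=200.0, sigma=3.0, background=10.0, shape=(200, 200)):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.full(shape, background)
    for cy, cx in centers:
        img += amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return img


class TestFindMaxima:
    CENTERS = [(30, 30), (30, 170), (170, 30), (170, 170), (100, 100)]

    def test_constant_image_no_maxima(self):
        assert len(find_maxima(np.full((30, 30), 9.0), 0.0)) == 0

    def test_five_peaks_recovered_within_one_pixel(self):
        img = _peaks_image(self.CENTERS)
        foci = find_maxima(img, 50.0)
        assert len(foci) == 5
        found = sorted((round(y), round(x)) for x, y in foci.points)
        assert found == sorted(self.CENTERS)

    def test_tolerance_above_all_prominences_gives_none(self):
        img = _peaks_image(self.CENTERS)
        assert len(find_maxima(img, 250.0)) == 0

    def test_count_monotone_in_tolerance(self, rng):
        img = _peaks_image(self.CENTERS) + rng.normal(0, 4, (200, 200))
        counts = [len(find_maxima(img, tol)) for tol in (5, 20, 60, 120, 260)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_plateau_yields_single_centroid_point(self):
        img = np.zeros((20, 20))
        img[5:8, 5:9] = 10.0
        foci = find_maxima(img, 3.0)
        assert len(foci) == 1
        (x, y) = foci.points[0]
        assert (x, y) == (6.5, 6.0)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            find_maxima(np.zeros((4, 4)), -1)


class TestAssignFoci:
    def _masks(self):
        nuclei = np.zeros((40, 40), bool)
        nuclei[5:15, 5:15] = True
        cyto = np.zeros((40, 40), bool)
        cyto[5:25, 5:25] = True  # contains the nucleus
        return nuclei, cyto

    def test_all_inside_nuclei(self):
        nuclei, cyto = self._masks()
        foci = FociSet([(7.0, 7.0), (10.0, 10.0)], 50)
        out = assign_foci(foci, nuclei, cyto)
        assert (out["nuclear"], out["cytoplasmic"], out["total"]) == (2, 0, 2)

    def test_compartment_split_with_outside_focus(self):
        nuclei, cyto = self._masks()
        pts = [(7, 7), (8, 9), (9, 7), (20, 20), (18, 22), (35, 35)]
        out = assign_foci(FociSet([(float(x), float(y)) for x, y in pts], 50), nuclei, cyto)
        assert out["nuclear"] == 3 and out["cytoplasmic"] == 2
        assert out["total"] == 5          # the outside focus is excluded
        assert out["unassigned"] == 1

    def test_no_cytoplasm_total_includes_outside(self):
        nuclei, _ = self._masks()
        pts = [(7, 7), (8, 9), (9, 7), (35, 35)]
        out = assign_foci(FociSet([(float(x), float(y)) for x, y in pts], 50), nuclei, None)
        assert out["nuclear"] == 3 and out["cytoplasmic"] == 0 and out["total"] == 4

    def test_counts_bounded_by_foci(self, rng):
        nuclei, cyto = self._masks()
        pts = [(float(x), float(y)) for x, y in rng.uniform(0, 39, (25, 2))]
        out = assign_foci(FociSet(pts, 10), nuclei, cyto)
        assert 0 <= out["nuclear"] + out["cytoplasmic"] <= out["total"] + out["unassigned"]
        assert out["total"] <= len(pts)
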