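"""Erf boundary fitting, registration, domain metrics and retraction."""

import numpy as np
import pytest
from conftest import grid_oracle_double, grid_oracle_single

from parquant import (GroundTruth, boundary_offset, domain_change_ratio,
                      domain_metrics, erf_boundary, erf_two_boundaries,
                      fit_double_boundary, fit_single_boundary,
                      gen_membrane_profile, mark_registered,
                      register_profiles, retraction, segregation_efficiency)
from parquant.boundaries import DomainMetrics, DoubleBoundaryFit


class TestSingleBoundaryFit:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(0, 1, 120)
        y = erf_boundary(x, 0.5, 1.0, 30.0, 0.6)
        fit = fit_single_boundary(x, y, normalize=False)
        assert fit.converged
        for got, want in [(fit.a, 0.5), (fit.b, 1.0), (fit.m, 30.0),
                          (fit.c, 0.6)]:
            assert abs(got - want) <= 1e-6

    def test_minmax_normalization_preserves_c_and_m(self):
        x = np.linspace(0, 1, 120)
        y = erf_boundary(x, 40.0, 25.0, 30.0, 0.6)
        fit = fit_single_boundary(x, y)   # internal min-max normalization
        assert abs(fit.c - 0.6) <= 1e-6
        assert abs(fit.m - 30.0) <= 1e-4

    def test_rss_never_exceeds_grid_oracle(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0, 1, 80)
        for _ in range(5):
            c = rng.uniform(0.2, 0.8)
            m = rng.uniform(10, 60)
            y = erf_boundary(x, 0.3, 1.0, m, c) + rng.normal(0, 0.05, len(x))
            fit = fit_single_boundary(x, y, normalize=False)
            assert fit.rss <= grid_oracle_single(x, y) + 1e-12

    def test_mirror_symmetry(self):
        x = np.linspace(0, 1, 120)
        y = erf_boundary(x, 0.5, 1.0, 30.0, 0.6)
        mirrored = y[::-1]                      # profile at x -> 1 - x
        fit = fit_single_boundary(x, mirrored, normalize=False)
        assert fit.c == pytest.approx(0.4, abs=1e-6)
        assert fit.b == pytest.approx(-1.0, abs=1e-6)

    def test_flat_segment_unconverged(self):
        x = np.linspace(0, 1, 50)
        fit = fit_single_boundary(x, np.full(50, 0.7))
        assert not fit.converged
        assert np.isnan(fit.c)

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError):
            fit_single_boundary(np.linspace(0, 1, 5), np.zeros(5))


class TestRegistration:
    """Full profiles are circular; the reference boundary is fitted on a
    half-window around it (the half-profile split), then both channels
    are rolled so it lands at the canonical position 0.5."""

    N = 200

    @classmethod
    def _circular_pair(cls, c_ref, offset=0.0):
        x = np.arange(cls.N) / cls.N
        ref = erf_two_boundaries(x, 1.5, -1.2, 60.0, c_ref, 0.85)
        other = erf_two_boundaries(x, 1.5, -1.2, 60.0, c_ref + offset, 0.85)
        return x, ref, other

    @classmethod
    def _fit_window(cls, x, y, around):
        win = np.abs(x - around) < 0.2
        return fit_single_boundary(x[win], y[win])

    def test_canonical_pair_zero_shift(self):
        x, ref, other = self._circular_pair(0.5)
        fit = self._fit_window(x, ref, 0.5)
        aligned, shifts = register_profiles([fit], [(ref, other)])
        assert shifts[0] == pytest.approx(0.0)
        assert np.allclose(aligned[0][0], ref)

    def test_idempotence_under_input_shift(self):
        """Pre-shifting the pair then registering gives the same output."""
        x, ref, other = self._circular_pair(0.4)
        k = 20                                   # circular shift of 0.1
        ref_s, other_s = np.roll(ref, k), np.roll(other, k)
        fit = self._fit_window(x, ref, 0.4)
        fit_s = self._fit_window(x, ref_s, 0.5)
        out1, _ = register_profiles([fit], [(ref, other)])
        out2, _ = register_profiles([fit_s], [(ref_s, other_s)])
        assert np.allclose(out1[0][0], out2[0][0], atol=1e-9)
        assert np.allclose(out1[0][1], out2[0][1], atol=1e-9)

    def test_channel_offset_survives_registration(self):
        delta = 0.05
        x, ref, other = self._circular_pair(0.35, offset=delta)
        fit = self._fit_window(x, ref, 0.35)
        aligned, _ = register_profiles([fit], [(ref, other)])
        fit2 = self._fit_window(x, aligned[0][1], 0.55)
        assert fit2.c == pytest.approx(0.5 + delta, abs=0.005)

    def test_unconverged_reference_excluded(self):
        x = np.arange(100) / 100
        flat = np.full(100, 0.5)
        fit = fit_single_boundary(x, flat)
        with pytest.warns(UserWarning, match="excluded"):
            aligned, shifts = register_profiles([fit], [(flat, flat)])
        assert aligned[0] is None and np.isnan(shifts[0])


class TestBoundaryOffset:
    @staticmethod
    def _fit(c):
        x = np.linspace(0, 1, 100)
        return mark_registered(
            fit_single_boundary(x, erf_boundary(x, 0.5, 1.0, 40.0, c),
                                normalize=False))

    def test_identical_fits_zero(self):
        f = self._fit(0.5)
        assert boundary_offset(f, f, 100.0) == pytest.approx(0.0, abs=1e-8)

    def test_scaling_to_micrometers(self):
        assert boundary_offset(self._fit(0.50), self._fit(0.52), 100.0) \
            == pytest.approx(2.0, abs=1e-4)

    def test_unregistered_inputs_rejected(self):
        x = np.linspace(0, 1, 100)
        f = fit_single_boundary(x, erf_boundary(x, 0.5, 1.0, 40.0, 0.5),
                                normalize=False)
        with pytest.raises(ValueError, match="registered"):
            boundary_offset(f, f, 100.0)


class TestDoubleBoundaryFit:
    def test_noiseless_exact_recovery(self):
        truth = GroundTruth(baseline_a=0.2, amplitude_b=1.5, slope_m=40.0,
                            boundary_c1=0.35, boundary_c2=0.75)
        prof = gen_membrane_profile(truth, n_points=256)
        fit = fit_double_boundary((prof.x, prof.membrane))
        assert fit.converged
        for got, want in [(fit.a, 0.2), (fit.b, 1.5), (fit.m, 40.0),
                          (fit.c1, 0.35), (fit.c2, 0.75)]:
            assert abs(got - want) <= 1e-5

    def test_flat_profile_unconverged(self):
        x = np.arange(64) / 64
        fit = fit_double_boundary((x, np.full(64, 0.3)))
        assert not fit.converged
        assert np.isnan(fit.c1) and np.isnan(fit.c2)

    def test_rss_never_exceeds_grid_oracle(self):
        rng = np.random.default_rng(7)
        x = np.arange(128) / 128
        for _ in range(5):
            c1 = rng.uniform(0.1, 0.4)
            c2 = rng.uniform(c1 + 0.2, 0.9)
            m = rng.uniform(20, 60)
            y = erf_two_boundaries(x, 0.2, 1.0, m, c1, c2) \
                + rng.normal(0, 0.05, len(x))
            fit = fit_double_boundary((x, y))
            assert fit.rss <= grid_oracle_double(x, y, m) + 1e-12

    def test_circular_shift_equivariance(self):
        """Rolling the profile shifts c1, c2 (mod 1) without changing
        domain sizes."""
        truth = GroundTruth(baseline_a=0.2, amplitude_b=1.5, slope_m=40.0,
                            boundary_c1=0.35, boundary_c2=0.75)
        prof = gen_membrane_profile(truth, n_points=256)
        fit0 = fit_double_boundary((prof.x, prof.membrane))
        for k in (32, 100, 180):
            rolled = np.roll(prof.membrane, k)
            fit = fit_double_boundary((prof.x, rolled))
            size0 = fit0.c2 - fit0.c1
            size = (fit.c2 - fit.c1) if fit.b * fit0.b > 0 \
                else 1.0 - (fit.c2 - fit.c1)
            assert size == pytest.approx(size0, abs=1e-4)

    def test_anterior_marker_negative_amplitude(self):
        truth = GroundTruth(baseline_a=1.5, amplitude_b=-1.2, slope_m=35.0,
                            boundary_c1=0.3, boundary_c2=0.7)
        prof = gen_membrane_profile(truth, n_points=256)
        fit = fit_double_boundary((prof.x, prof.membrane))
        assert fit.b == pytest.approx(-1.2, abs=1e-5)
        assert fit.c1 == pytest.approx(0.3, abs=1e-5)


class TestDomainMetrics:
    @staticmethod
    def _fit(c1, c2, b=1.0):
        return DoubleBoundaryFit(a=0.0, b=b, m=40.0, c1=c1, c2=c2, rss=0.0,
                                 converged=True)

    def test_example_sizes(self):
        dm = domain_metrics(self._fit(0.3, 0.7))
        assert dm.posterior_size == pytest.approx(0.4)
        assert dm.anterior_size == pytest.approx(0.6)
        assert dm.posterior_center == pytest.approx(0.5)

    def test_degenerate_domain(self):
        dm = domain_metrics(self._fit(0.5, 0.5))
        assert dm.posterior_size == 0.0 and dm.anterior_size == 1.0

    def test_sizes_sum_to_one_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            c1 = rng.uniform(0, 0.9)
            c2 = rng.uniform(c1, 1.0)
            dm = domain_metrics(self._fit(c1, c2))
            assert dm.posterior_size + dm.anterior_size == 1.0

    def test_change_ratio(self):
        before = DomainMetrics(0.4, 0.6, 0.5)
        after = DomainMetrics(0.2, 0.8, 0.5)
        assert domain_change_ratio(before, before) == 1.0
        assert domain_change_ratio(before, after) == pytest.approx(0.5)

    def test_change_ratio_zero_before_flagged(self):
        zero = DomainMetrics(0.0, 1.0, 0.5)
        with pytest.warns(UserWarning):
            assert np.isnan(domain_change_ratio(zero, zero))

    def test_segregation_efficiency(self):
        fit = self._fit(0.25, 0.75, b=-1.0)
        assert segregation_efficiency(fit) == pytest.approx(0.5)
        with pytest.warns(UserWarning, match="anterior-marker"):
            segregation_efficiency(self._fit(0.25, 0.75, b=1.0))

    def test_segregation_monotone_in_truth(self):
        """Shrinking true anterior domain -> decreasing efficiency score."""
        vals = []
        for width in (0.3, 0.45, 0.6, 0.75):
            c1 = 0.5 - width / 2
            truth = GroundTruth(baseline_a=1.5, amplitude_b=-1.2,
                                slope_m=40.0, boundary_c1=c1,
                                boundary_c2=c1 + width)
            prof = gen_membrane_profile(truth, n_points=256)
            fit = fit_double_boundary((prof.x, prof.membrane))
            vals.append(segregation_efficiency(fit))
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestRetraction:
    def test_domain_line_through_pole(self):
        d = retraction((0, 0), (50, 0), (50, -10), (50, 10))
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_worked_geometry(self):
        d = retraction((0, 0), (50, 0), (30, -10), (30, 10))
        assert d == pytest.approx(20.0)

    def test_pixel_size_scaling(self):
        d = retraction((0, 0), (50, 0), (30, -10), (30, 10), pixel_size=0.2)
        assert d == pytest.approx(4.0)

    def test_parallel_lines_raise(self):
        with pytest.raises(ValueError, match="parallel"):
            retraction((0, 0), (50, 0), (10, 5), (20, 5))

    def test_intersection_outside_segment_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            retraction((0, 0), (50, 0), (80, -10), (80, 10))

    def test_retraction_difference_roundtrip(self):
        r1 = retraction((0, 0), (50, 0), (30, -10), (30, 10))
        r2 = retraction((0, 0), (50, 0), (38, -10), (38, 10))
        assert r1 - r2 == pytest.approx(8.0)
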