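"""Density-profile primitives: binning, peaks, intercepts, uncertainties."""

import numpy as np
import pytest

from memdiffkit import (
    AnalysisError,
    InterceptError,
    SelectionError,
    block_average,
    bootstrap_scalar,
    bootstrap_series,
    density_profile,
    generate_bilayer_ensemble,
    peak_location,
    profile_intercept,
)
from memdiffkit.profiles import DensityProfile, _smooth3, peak_z, symmetric_edges
from memdiffkit.synth import BilayerSpec

from conftest import make_ensemble


def analytic_profile(fn, half=4.0, bin_width=0.1, label="analytic"):
    edges = symmetric_edges(half, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(edges, fn(centers), label, 1)


class TestDensityProfile:
    def test_single_particle_normalisation(self):
        ens = make_ensemble([[0.02]], box=(5.0, 5.0, 10.0))
        prof = density_profile(ens, {"role": "water_oxygen"}, bin_width=0.1)
        i = np.argmin(np.abs(prof.centers - 0.05))
        assert prof.density[i] == pytest.approx(1.0 / (25.0 * 0.1))
        assert np.count_nonzero(prof.density) == 1

    def test_uniform_box_gives_flat_profile(self):
        rng = np.random.default_rng(42)
        n = 10_000
        ens = make_ensemble([rng.uniform(-5.0, 5.0, n)], box=(5.0, 5.0, 10.0))
        prof = density_profile(ens, {"role": "water_oxygen"}, bin_width=0.5)
        expected = n / (25.0 * 10.0)
        per_bin = n / len(prof.density)
        sigma = np.sqrt(per_bin) / (25.0 * 0.5)  # Poisson counting noise
        assert np.all(np.abs(prof.density - expected) < 5 * sigma)

    def test_conservation_of_counts(self, plain_ensemble):
        # constant-area check on a manual ensemble
        rng = np.random.default_rng(1)
        ens = make_ensemble([rng.uniform(-4, 4, 500) for _ in range(5)])
        prof = density_profile(ens, {"role": "water_oxygen"}, bin_width=0.13)
        total = prof.density.sum() * prof.bin_width * prof.mean_area
        assert total == pytest.approx(500.0, rel=1e-6)

    def test_phosphate_peaks_near_generator_positions(self, plain_ensemble):
        prof = density_profile(plain_ensemble, {"role": "phosphate"}, 0.1)
        half = prof.bin_edges[-1]
        up = peak_z(prof, (0.1, half))
        lo = peak_z(prof, (-half, -0.1))
        assert abs(up - 1.9) < 0.1
        assert abs(lo + 1.9) < 0.1

    def test_empty_selection_raises_named_error(self, plain_ensemble):
        with pytest.raises(SelectionError, match="ETHANOL"):
            density_profile(plain_ensemble, {"species": "ETHANOL"}, 0.1)


class TestPeakLocation:
    def test_symmetric_gaussian_peak(self):
        prof = analytic_profile(lambda z: np.exp(-((z - 1.25) ** 2) / (2 * 0.3**2)))
        est = peak_location(prof, (0.0, 3.0))
        assert est.value == pytest.approx(1.25, abs=0.05)

    def test_search_masking_selects_leaflet(self):
        fn = lambda z: np.exp(-((z - 1.5) ** 2) / 0.08) + np.exp(-((z + 1.5) ** 2) / 0.08)
        prof = analytic_profile(fn)
        up = peak_location(prof, (0.0, 4.0))
        lo = peak_location(prof, (-4.0, 0.0))
        assert up.value == pytest.approx(1.5, abs=0.05)
        assert lo.value == pytest.approx(-1.5, abs=0.05)

    def test_flat_profile_has_no_distinct_peak(self):
        from memdiffkit import NoDistinctPeakError

        prof = analytic_profile(lambda z: np.ones_like(z))
        with pytest.raises(NoDistinctPeakError):
            peak_location(prof, (-2.0, 2.0))

    def test_bootstrap_interval_covers_generating_peak(self):
        covered = 0
        for s in range(20):
            ens = generate_bilayer_ensemble(
                BilayerSpec.small(seed=400 + s, n_frames=60, n_water=300,
                                  interior_water_target=10)
            )
            prof = density_profile(
                ens, {"species": "POPI", "role": "glycerol_backbone"}, 0.1
            )
            est = peak_location(prof, (0.5, 3.0), seed=s)
            covered += est.lower <= 1.6 <= est.upper
        assert covered >= 16


class TestProfileIntercept:
    def test_equal_gaussians_cross_midway(self):
        a = analytic_profile(lambda z: np.exp(-(z**2) / 0.5))
        b = analytic_profile(lambda z: np.exp(-((z - 1.2) ** 2) / 0.5))
        est = profile_intercept(a, b, (0.0, 1.2))
        assert est.value == pytest.approx(0.6, abs=0.01)

    def test_piecewise_linear_crossing_is_exact(self):
        a = analytic_profile(lambda z: np.clip(2.0 - z, 0, None))
        b = analytic_profile(lambda z: np.clip(z - 2.0 + 2.4, 0, None))
        # a - b is linear with root at z = 0.8; interpolation resolves exactly
        est = profile_intercept(a, b, (0.0, 1.6))
        assert est.value == pytest.approx(0.8, abs=1e-12)

    def test_matches_dense_grid_brute_force(self):
        a = analytic_profile(lambda z: 1.0 / (1.0 + np.exp(-3 * (z - 0.7))))
        b = analytic_profile(lambda z: np.exp(-(z**2) / 2.3))
        est = profile_intercept(a, b, (-1.0, 3.0))
        # oracle: dense scan of the same smoothed binned difference
        centers = a.centers
        diff = _smooth3(a.density - b.density)
        zz = np.linspace(-1.0, 3.0, 200001)
        dd = np.interp(zz, centers, diff)
        sign_change = np.nonzero(np.sign(dd[:-1]) * np.sign(dd[1:]) < 0)[0]
        oracle = zz[sign_change[0]]
        assert abs(est.value - oracle) < a.bin_width / 100

    def test_intercept_is_symmetric(self):
        a = analytic_profile(lambda z: np.exp(-(z**2)))
        b = analytic_profile(lambda z: 0.4 * np.ones_like(z))
        ab = profile_intercept(a, b, (0.0, 3.0)).value
        ba = profile_intercept(b, a, (0.0, 3.0)).value
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_no_crossing_and_multiple_crossings_error(self):
        a = analytic_profile(lambda z: np.ones_like(z))
        b = analytic_profile(lambda z: np.zeros_like(z))
        with pytest.raises(InterceptError, match="do not cross"):
            profile_intercept(a, b, (-2.0, 2.0))
        c = analytic_profile(lambda z: np.cos(3 * z))
        d = analytic_profile(lambda z: np.zeros_like(z))
        with pytest.raises(InterceptError, match="multiple") as exc:
            profile_intercept(c, d, (-2.0, 2.0))
        assert len(exc.value.candidates) > 1


class TestBootstrap:
    def test_frame_count_functional_is_degenerate(self, plain_ensemble):
        est = bootstrap_scalar(plain_ensemble, lambda e: e.n_frames, n_boot=20, seed=0)
        assert est.lower == est.upper == est.value == plain_ensemble.n_frames

    def test_same_seed_reproduces_interval(self, plain_ensemble):
        f = lambda e: float(e.boxes[:, 0].mean())
        a = bootstrap_scalar(plain_ensemble, f, n_boot=25, seed=9)
        b = bootstrap_scalar(plain_ensemble, f, n_boot=25, seed=9)
        assert (a.lower, a.value, a.upper) == (b.lower, b.value, b.upper)

    def test_interval_width_matches_normal_theory(self):
        rng = np.random.default_rng(0)
        widths = []
        n = 100
        for _ in range(10):
            x = rng.normal(0.0, 1.0, n)
            widths.append(bootstrap_series(x, np.mean, n_boot=200, rng=rng).width)
        expected = 2 * 1.96 / np.sqrt(n)
        assert abs(np.mean(widths) - expected) / expected < 0.3

    def test_width_shrinks_like_inverse_sqrt_n(self):
        rng = np.random.default_rng(3)
        sizes = [50, 100, 200, 400]
        log_w = []
        for n in sizes:
            w = [
                bootstrap_series(rng.normal(0, 1, n), np.mean, n_boot=150, rng=rng).width
                for _ in range(8)
            ]
            log_w.append(np.log(np.mean(w)))
        slope = np.polyfit(np.log(sizes), log_w, 1)[0]
        assert -0.65 < slope < -0.35

    def test_rejects_too_few_resamples(self, plain_ensemble):
        with pytest.raises(AnalysisError):
            bootstrap_scalar(plain_ensemble, lambda e: 0.0, n_boot=1)


class TestBlockAverage:
    def test_constant_series_has_zero_width(self):
        est = block_average(np.full(50, 3.3), n_blocks=5)
        assert est.value == pytest.approx(3.3)
        assert est.width == pytest.approx(0.0)

    def test_iid_normal_coverage_near_nominal(self):
        rng = np.random.default_rng(12)
        covered = sum(
            est.lower <= 0.0 <= est.upper
            for est in (
                block_average(rng.normal(0, 1, 100), 5) for _ in range(300)
            )
        )
        assert 0.90 <= covered / 300 <= 0.99

    def test_ar1_interval_wider_than_naive(self):
        rng = np.random.default_rng(5)
        phi = 0.9
        ratios = []
        for _ in range(20):
            eps = rng.normal(0, 1, 400)
            x = np.empty(400)
            x[0] = eps[0]
            for i in range(1, 400):
                x[i] = phi * x[i - 1] + eps[i]
            blocked = block_average(x, 5).width
            naive = 2 * 1.96 * x.std(ddof=1) / np.sqrt(len(x))
            ratios.append(blocked / naive)
        assert np.mean(ratios) > 1.5

    def test_short_series_rejected(self):
        with pytest.raises(AnalysisError):
            block_average(np.arange(9), n_blocks=5)
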