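"""Phosphene pattern generation, calibration, and window queries."""

import json

import numpy as np
import pytest
from scipy import stats

from phosim.patterns import (
    CENTRAL_RADIUS_DEG,
    HIGH_WINDOW_CALIBRATION,
    TIERS,
    Circle,
    DensityProfile,
    PhosphenePattern,
    Rect,
    count_in_window,
    fit_density_profile,
    generate_pattern,
    perceptual_efficiency,
    phosphene_sigma,
)


class TestSigmaLaw:
    @pytest.mark.parametrize("rho,sigma", [(0.0, 0.083), (10.0, 0.513)])
    def test_known_values(self, rho, sigma):
        assert phosphene_sigma(rho) == pytest.approx(sigma)

    def test_half_degree_phosphenes_at_ten_degrees(self):
        # a phosphene ~0.5 deg across at 10 deg eccentricity
        assert 2 * phosphene_sigma(10.0) == pytest.approx(1.0, abs=0.05)
        assert phosphene_sigma(10.0) == pytest.approx(0.5, abs=0.05)

    def test_negative_eccentricity_rejected(self):
        with pytest.raises(ValueError):
            phosphene_sigma(-0.1)

    def test_every_generated_phosphene_obeys_the_law(self, tier_patterns):
        for pats in tier_patterns.values():
            p = pats[0]
            expected = 0.043 * p.eccentricity_deg + 0.083
            assert np.allclose(p.sigma_deg, expected, atol=1e-9)
            assert np.all(p.sigma_deg >= 0.083 - 1e-12)


class TestGeneration:
    @pytest.mark.parametrize("tier", list(TIERS))
    def test_exact_totals_and_central_counts_every_seed(self, profile, tier):
        t = TIERS[tier]
        for seed in (0, 1, 17, 999):
            p = generate_pattern(tier, profile, seed=seed)
            assert len(p) == t.total
            assert count_in_window(p, Circle(CENTRAL_RADIUS_DEG)) == t.central

    def test_same_seed_reproduces_pattern(self, profile):
        a = generate_pattern("medium", profile, seed=7)
        b = generate_pattern("medium", profile, seed=7)
        assert np.array_equal(a.x_deg, b.x_deg)
        assert np.array_equal(a.y_deg, b.y_deg)
        assert np.array_equal(a.sigma_deg, b.sigma_deg)

    def test_different_seeds_differ(self, profile):
        a = generate_pattern("medium", profile, seed=1)
        b = generate_pattern("medium", profile, seed=2)
        assert not np.array_equal(a.x_deg, b.x_deg)

    def test_unknown_tier_rejected(self, profile):
        with pytest.raises(ValueError, match="tier"):
            generate_pattern("ultra", profile, seed=0)

    def test_angles_uniform_in_aggregate(self, profile):
        # chi-square on 12 angular bins pooled over 50 seeds
        angles = np.concatenate(
            [
                np.arctan2(p.y_deg, p.x_deg)
                for p in (generate_pattern("low", profile, seed=s) for s in range(50))
            ]
        )
        counts, _ = np.histogram(angles, bins=12, range=(-np.pi, np.pi))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_radial_density_non_increasing_within_strata(self, profile):
        """Ring densities decrease with eccentricity inside each stratum.

        The published central/total split together with the central
        window counts cannot be met by one monotone radial profile, so
        the construction is stratified at 10 deg and monotonicity holds
        within each stratum rather than across the boundary.
        """
        rho = np.concatenate(
            [
                generate_pattern("high", profile, seed=s).eccentricity_deg
                for s in range(30)
            ]
        )
        for edges in (np.linspace(0, 10, 6), np.linspace(10, 45, 8)):
            counts, _ = np.histogram(rho, bins=edges)
            areas = np.pi * np.diff(edges**2)
            density = counts / areas
            assert np.all(np.diff(density) <= 1e-12 + 0.05 * density[:-1])


class TestWindowCounts:
    def test_matches_exhaustive_scan_oracle(self, profile, rng):
        p = generate_pattern("medium", profile, seed=3)
        for _ in range(100):
            if rng.random() < 0.5:
                w = Circle(float(rng.uniform(0.1, 20)))
                expected = int(
                    sum(
                        1
                        for x, y in zip(p.x_deg, p.y_deg)
                        if (x * x + y * y) ** 0.5 <= w.radius_deg
                    )
                )
            else:
                w = Rect(float(rng.uniform(0.1, 25)), float(rng.uniform(0.1, 25)))
                expected = int(
                    sum(
                        1
                        for x, y in zip(p.x_deg, p.y_deg)
                        if abs(x) <= w.width_deg / 2 and abs(y) <= w.height_deg / 2
                    )
                )
            assert count_in_window(p, w) == expected

    def test_empty_pattern_and_membership(self, profile):
        empty = PhosphenePattern(
            "high", 0, 45.0, profile, np.array([]), np.array([]), np.array([])
        )
        assert count_in_window(empty, Circle(5.0)) == 0
        single = PhosphenePattern(
            "high",
            0,
            45.0,
            profile,
            np.array([0.0]),
            np.array([0.0]),
            np.array([0.083]),
        )
        assert count_in_window(single, Rect(1.0, 1.0)) == 1
        shifted = PhosphenePattern(
            "high",
            0,
            45.0,
            profile,
            np.array([5.0]),
            np.array([5.0]),
            np.array([0.4]),
        )
        assert count_in_window(shifted, Rect(1.0, 1.0)) == 0


class TestDensityProfileFit:
    def test_uniform_limit_amplitude_is_count_over_area(self):
        fit = fit_density_profile([(Circle(10.0), 314.159265)], rho_max_deg=45.0)
        assert fit.profile.exponent == 0.0
        assert fit.profile.amplitude == pytest.approx(1.0, rel=1e-6)

    def test_expected_count_matches_grid_quadrature_oracle(self, profile):
        # brute-force midpoint-grid summation of the density over regions
        for region in (Rect(5.7, 5.7), Rect(10.0, 3.5), Circle(4.0)):
            if isinstance(region, Rect):
                hw, hh = region.width_deg / 2, region.height_deg / 2
            else:
                hw = hh = region.radius_deg
            n = 801
            xs = np.linspace(-hw, hw, n)
            ys = np.linspace(-hh, hh, n)
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            d = profile.density(np.hypot(X, Y))
            if isinstance(region, Circle):
                d = np.where(np.hypot(X, Y) <= region.radius_deg, d, 0.0)
            brute = d.mean() * (2 * hw) * (2 * hh)
            assert profile.expected_count(region) == pytest.approx(brute, rel=5e-3)

    def test_calibrated_expected_window_counts_within_15_percent(self, profile_fit):
        assert np.all(np.abs(profile_fit.relative_residuals) <= 0.15)
        assert not profile_fit.flagged

    def test_infeasible_constraints_are_flagged_not_fatal(self):
        # nested circles demanding *fewer* phosphenes in a larger region
        # cannot be met by any non-negative density
        fit = fit_density_profile(
            [(Circle(5.0), 500.0), (Circle(10.0), 300.0), (Circle(20.0), 200.0)],
            rho_max_deg=45.0,
        )
        assert fit.flagged

    def test_stratified_fit_rejects_windows_outside_boundary(self):
        with pytest.raises(ValueError, match="central boundary"):
            fit_density_profile(
                [(Rect(30.0, 30.0), 100.0)] * 3,
                central=(10.0, 381, 1757),
            )

    def test_realized_window_means_track_published_counts(self, tier_patterns):
        # across-seed means against the printed calibration constraints:
        # systematic offset bounded by the fit band, sampling by 3 SE
        for win, target in HIGH_WINDOW_CALIBRATION:
            counts = np.array(
                [count_in_window(p, win) for p in tier_patterns["high"]], dtype=float
            )
            se = counts.std(ddof=1) / np.sqrt(len(counts))
            assert abs(counts.mean() - target) <= 0.15 * target + 3 * se

    def test_medium_low_share_the_high_profile_shape(self, tier_patterns):
        # the same 5.7 deg window tracks the published counts for the
        # rescaled Medium and Low tiers
        for tier, target in (("medium", 134.0), ("low", 73.0)):
            counts = np.array(
                [count_in_window(p, Rect(5.7, 5.7)) for p in tier_patterns[tier]],
                dtype=float,
            )
            se = counts.std(ddof=1) / np.sqrt(len(counts))
            assert abs(counts.mean() - target) <= 0.15 * target + 3 * se


class TestPerceptualEfficiency:
    def test_equals_exhaustive_recount(self, tier_patterns):
        p = tier_patterns["high"][0]
        acuity = 1.07
        radius = 5 * 10**acuity / 60 / 2
        brute = int(
            sum(
                1
                for x, y in zip(p.x_deg, p.y_deg)
                if (x * x + y * y) ** 0.5 <= radius
            )
        )
        assert perceptual_efficiency(p, acuity) == brute

    def test_empty_circle_gives_zero(self, profile):
        p = PhosphenePattern(
            "low",
            0,
            45.0,
            profile,
            np.array([10.0]),
            np.array([10.0]),
            np.array([0.7]),
        )
        assert perceptual_efficiency(p, 1.0) == 0


class TestSerialization:
    def test_json_round_trip(self, profile):
        p = generate_pattern("low", profile, seed=5)
        q = PhosphenePattern.from_json(p.to_json())
        assert q.tier == p.tier and q.seed == p.seed
        assert np.allclose(q.x_deg, p.x_deg)
        assert np.allclose(q.sigma_deg, p.sigma_deg)
        assert q.profile.rho0 == pytest.approx(p.profile.rho0)

    def test_csv_has_header_and_all_rows(self, profile):
        p = generate_pattern("low", profile, seed=5)
        lines = p.to_csv().strip().splitlines()
        assert lines[0] == "x_deg,y_deg,sigma_deg"
        assert len(lines) == len(p) + 1

    def test_profile_dict_round_trip(self, profile):
        d = json.loads(json.dumps(profile.to_dict()))
        q = DensityProfile.from_dict(d)
        assert q == profile
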