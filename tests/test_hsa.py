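"""Harmonic superposition thermodynamics: closed forms, oracles, features."""

import numpy as np
import pytest

from hexscape.database import DatabaseError, StationaryPointDatabase
from hexscape.hsa import (
    ContributionSet,
    FeatureConfig,
    ThermoCurve,
    detect_features,
    feature_contributions,
    first_feature_temperature,
    heat_capacity_curve,
    log_partition_function,
    log_weight,
    occupation_derivatives,
    occupation_probabilities,
    temperature_grid,
)

from conftest import make_random_db

#: argmax of x^2 e^x / (1+e^x)^2 -- the two-state (Schottky) peak position
SCHOTTKY_X = 2.399357280515145


class TestLogWeight:
    def test_equal_minima_equal_weights(self):
        for kbt in (0.01, 0.3, 5.0):
            w1 = log_weight(1.0, 0.5, 2.0, 7, kbt)
            w2 = log_weight(1.0, 0.5, 2.0, 7, kbt)
            assert w1 == w2

    def test_doubled_degeneracy_adds_ln2(self):
        base = log_weight(0.7, 0.1, 1.0, 4, 0.2)
        assert log_weight(0.7, 0.1, 2.0, 4, 0.2) == pytest.approx(
            base + np.log(2.0), abs=1e-14
        )

    def test_boltzmann_limit_low_temperature(self):
        # E_b > E_a: weight ratio w_b / w_a -> 0 as kBT -> 0+
        for kbt in (0.1, 0.01, 0.001):
            ratio = log_weight(1.0, 0.0, 1.0, 3, kbt) - log_weight(0.0, 0.0, 1.0, 3, kbt)
            assert ratio == pytest.approx(-1.0 / kbt)
        assert np.exp(log_weight(1.0, 0.0, 1.0, 3, 1e-4)
                      - log_weight(0.0, 0.0, 1.0, 3, 1e-4)) == 0.0


class TestOccupations:
    def test_single_minimum_probability_one(self):
        db = StationaryPointDatabase(kappa=3)
        db.add_minimum(0.0)
        assert occupation_probabilities(db, 0.5)[0] == pytest.approx(1.0, abs=1e-15)

    def test_two_identical_minima_half_each(self):
        db = StationaryPointDatabase(kappa=3)
        db.add_minimum(1.0, 0.2)
        db.add_minimum(1.0, 0.2)
        assert np.allclose(occupation_probabilities(db, 0.7), [0.5, 0.5], atol=1e-15)

    def test_two_state_matches_high_precision_oracle(self):
        """Independent arbitrary-precision evaluation via sympy."""
        import sympy

        d_e, d_l, n_ratio, kappa = 0.4, 0.8, 3.0, 6
        db = StationaryPointDatabase(kappa=kappa)
        db.add_minimum(0.0, 0.0, 1.0)
        db.add_minimum(d_e, d_l, n_ratio)
        for kbt in np.geomspace(0.02, 3.0, 10):
            t = sympy.Float(kbt, 50)
            w1 = sympy.exp(-sympy.Integer(0) / t)
            w2 = sympy.Integer(3) * sympy.exp(-sympy.Float(d_e, 50) / t) * sympy.exp(
                -sympy.Float(d_l, 50)
            )
            expected = float(w2 / (w1 + w2))
            got = occupation_probabilities(db, float(kbt))[1]
            assert got == pytest.approx(expected, abs=1e-13)

    def test_empty_database_rejected(self):
        with pytest.raises(DatabaseError):
            occupation_probabilities(StationaryPointDatabase(kappa=1), 0.5)

    def test_limits(self):
        rng = np.random.default_rng(0)
        db = make_random_db(rng, n_minima=12, kappa=4)
        p_cold = occupation_probabilities(db, 1e-4)
        assert p_cold[np.argmin(db.energies)] == pytest.approx(1.0, abs=1e-10)
        # kBT -> infinity: p_a -> n_a e^{-L_a} / sum_b n_b e^{-L_b}
        lw = np.array(
            [np.log(m.degeneracy) - m.log_freq_product for m in db.minima]
        )
        expected = np.exp(lw - lw.max())
        expected /= expected.sum()
        p_hot = occupation_probabilities(db, 1e6)
        assert np.allclose(p_hot, expected, atol=1e-6)


class TestHeatCapacity:
    def test_single_minimum_constant_kappa(self):
        db = StationaryPointDatabase(kappa=9)
        db.add_minimum(-2.0, 0.3)
        curve = heat_capacity_curve(db, temperature_grid(0.05, 2.0, 50))
        assert np.allclose(curve.cv, 9.0, atol=1e-12)

    def test_identical_minima_no_configurational_term(self):
        db = StationaryPointDatabase(kappa=4)
        for _ in range(3):
            db.add_minimum(1.5, 0.7, 2.0)
        curve = heat_capacity_curve(db, temperature_grid(0.05, 2.0, 50))
        assert np.allclose(curve.cv, 4.0, atol=1e-12)

    def test_two_state_closed_form_pointwise(self, two_state_db):
        grid = temperature_grid(0.01, 1.0, 300)
        curve = heat_capacity_curve(two_state_db, grid)
        x = 0.3 / grid
        closed = 5.0 + x**2 * np.exp(x) / (1.0 + np.exp(x)) ** 2
        assert np.max(np.abs(curve.cv - closed)) < 1e-10

    def test_matches_lnz_finite_differences(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            db = make_random_db(rng)
            grid = temperature_grid(0.05, 2.0, 30)
            curve = heat_capacity_curve(db, grid)
            for k, t in enumerate(grid[::5]):
                beta = 1.0 / t
                h = 3e-4 * beta
                lz = lambda b: float(log_partition_function(db, np.array([1.0 / b]))[0])
                d2 = (lz(beta + h) - 2 * lz(beta) + lz(beta - h)) / h**2
                cv_fd = beta**2 * d2
                assert abs(curve.cv[5 * k] - cv_fd) / abs(cv_fd) < 1e-6

    def test_occupations_normalised_everywhere(self):
        rng = np.random.default_rng(2)
        db = make_random_db(rng)
        curve = heat_capacity_curve(db, temperature_grid(0.02, 3.0, 100))
        assert np.max(np.abs(curve.occupations.sum(axis=1) - 1.0)) < 1e-12


class TestOccupationDerivatives:
    def test_single_minimum_zero(self):
        db = StationaryPointDatabase(kappa=2)
        db.add_minimum(0.0)
        assert occupation_derivatives(db, 0.4)[0] == pytest.approx(0.0, abs=1e-15)

    def test_two_state_sign_structure(self, two_state_db):
        for kbt in np.geomspace(0.02, 2.0, 12):
            dp = occupation_derivatives(two_state_db, kbt)
            assert dp[0] < 0 < dp[1]

    def test_sum_zero_everywhere(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            db = make_random_db(rng)
            for kbt in np.geomspace(0.02, 3.0, 20):
                assert abs(occupation_derivatives(db, kbt).sum()) < 1e-12

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(4)
        db = make_random_db(rng, n_minima=10, kappa=5)
        for kbt in (0.1, 0.3, 0.9):
            dp = occupation_derivatives(db, kbt)
            h = 1e-6 * kbt
            fd = (
                occupation_probabilities(db, kbt + h)
                - occupation_probabilities(db, kbt - h)
            ) / (2 * h)
            assert np.max(np.abs(dp - fd)) < 1e-6


def synthetic_curve(peaks, grid, width=0.02, kappa=0.0):
    """A CV curve constructed as Gaussian bumps at chosen kBT positions."""
    cv = np.full_like(grid, kappa)
    for loc, height in peaks:
        cv = cv + height * np.exp(-((grid - loc) ** 2) / (2 * width**2))
    return ThermoCurve(grid, cv, np.zeros_like(grid), np.zeros((len(grid), 1)), 0, [0])


class TestDetectFeatures:
    def test_threshold_discards_low_peak(self):
        grid = np.linspace(0.01, 0.5, 600)
        curve = synthetic_curve([(0.05, 3.0), (0.15, 2.0), (0.45, 5.0)], grid)
        cfg = FeatureConfig(threshold_low=0.086, exclude_melting=True)
        feats = [f for f in detect_features(curve, cfg) if f.kind == "peak"]
        assert feats and feats[0].kbt_location == pytest.approx(0.15, abs=2e-3)

    def test_monotone_curve_has_no_peaks(self):
        grid = np.linspace(0.01, 1.0, 200)
        curve = ThermoCurve(grid, 1.0 + grid, np.zeros_like(grid),
                            np.zeros((len(grid), 1)), 0, [0])
        feats = detect_features(curve, FeatureConfig(threshold_low=0.001,
                                                     exclude_melting=False))
        assert all(f.kind != "peak" for f in feats)

    def test_two_state_peak_matches_dense_scan(self, two_state_db):
        grid = temperature_grid(0.01, 1.0, 500)
        curve = heat_capacity_curve(two_state_db, grid)
        feats = [
            f
            for f in detect_features(
                curve, FeatureConfig(threshold_low=0.01, exclude_melting=False)
            )
            if f.kind == "peak"
        ]
        dense = temperature_grid(0.01, 1.0, 200_000)
        argmax = dense[np.argmax(heat_capacity_curve(two_state_db, dense).cv)]
        spacing = grid[feats[0].grid_index + 1] - grid[feats[0].grid_index - 1]
        assert abs(feats[0].kbt_location - argmax) <= spacing
        assert argmax == pytest.approx(0.3 / SCHOTTKY_X, rel=1e-4)

    def test_melting_exclusion_removes_highest_peak(self):
        grid = np.linspace(0.01, 0.6, 600)
        curve = synthetic_curve([(0.15, 2.0), (0.45, 5.0)], grid)
        with_melting = detect_features(curve, FeatureConfig(exclude_melting=False))
        without = detect_features(curve, FeatureConfig(exclude_melting=True))
        peak_locs = lambda fs: [f.kbt_location for f in fs if f.kind == "peak"]
        assert pytest.approx(0.45, abs=2e-3) in peak_locs(with_melting)
        assert all(abs(l - 0.45) > 0.01 for l in peak_locs(without))


class TestFeatureContributions:
    def test_two_state_full_coverage(self, two_state_db):
        grid = temperature_grid(0.01, 1.0, 300)
        curve = heat_capacity_curve(two_state_db, grid)
        cfg = FeatureConfig(threshold_low=0.01, exclude_melting=False)
        feats = [f for f in detect_features(curve, cfg) if f.kind == "peak"]
        f = feature_contributions(two_state_db, feats[0], cfg)
        assert [m for m, _ in f.positive_set.members] == [1]
        assert [m for m, _ in f.negative_set.members] == [0]
        assert f.positive_set.achieved_coverage == pytest.approx(1.0)

    def test_prefix_sets_match_brute_force(self):
        """Greedy prefixes equal the brute-force minimal covering prefixes."""
        rng = np.random.default_rng(5)
        db = make_random_db(rng, n_minima=20, kappa=3)
        kbt = 0.5
        dp = occupation_derivatives(db, kbt)
        from hexscape.hsa import FeatureReport

        feature = FeatureReport("peak", kbt, 0)
        cfg = FeatureConfig(coverage=0.98)
        f = feature_contributions(db, feature, cfg)
        for sign, cset in ((1, f.positive_set), (-1, f.negative_set)):
            group = [(i, v) for i, v in enumerate(dp) if np.sign(v) == sign]
            group.sort(key=lambda t: (-abs(t[1]), t[0]))
            total = sum(abs(v) for _, v in group)
            run, expected = 0.0, []
            for i, v in group:
                if run >= 0.98 * total:
                    break
                expected.append(i)
                run += abs(v)
            assert [m for m, _ in cset.members] == expected
            assert cset.achieved_coverage >= 0.98

    def test_full_coverage_includes_every_signed_minimum(self):
        rng = np.random.default_rng(6)
        db = make_random_db(rng, n_minima=15, kappa=2)
        kbt = 0.4
        from hexscape.hsa import FeatureReport

        f = feature_contributions(
            db, FeatureReport("peak", kbt, 0), FeatureConfig(coverage=1.0)
        )
        dp = occupation_derivatives(db, kbt)
        assert len(f.positive_set.members) == int(np.sum(dp > 0))
        assert len(f.negative_set.members) == int(np.sum(dp < 0))


class TestFirstFeature:
    def test_melting_only_database_reports_none(self):
        """A landscape whose only CV peak is the melting maximum is excluded."""
        db = StationaryPointDatabase(kappa=6)
        db.add_minimum(0.0)
        for _ in range(8):
            db.add_minimum(3.0, -5.0)  # entropic high-energy band only
        grid = temperature_grid(0.02, 2.0, 500)
        assert first_feature_temperature(db, grid, FeatureConfig()) is None

    def test_feature_above_window_reports_none(self, two_state_db):
        # gap 0.3 -> peak at ~0.125 and a slope inflection at ~0.061; with a
        # window of (0.07, 0.10) both fall outside, so nothing is reported
        grid = temperature_grid(0.02, 2.0, 500)
        cfg = FeatureConfig(threshold_low=0.07, threshold_high=0.10,
                            exclude_melting=False)
        assert first_feature_temperature(two_state_db, grid, cfg) is None

    def test_designed_two_funnel_feature_recovered(self):
        from hexscape.synth import FunnelSpec, generate_funnel_db

        db, manifest = generate_funnel_db(FunnelSpec(seed=42, target_feature_kbt=0.12))
        grid = temperature_grid(0.02, 1.5, 400)
        loc = first_feature_temperature(db, grid, FeatureConfig())
        spacing = np.max(np.diff(grid[(grid > 0.1) & (grid < 0.15)]))
        assert loc == pytest.approx(0.12, abs=2 * spacing)

    def test_gap_increase_shifts_peak_up(self):
        """Feature monotonicity on the two-state closed form."""
        locs = []
        for gap in (0.2, 0.3, 0.45):
            db = StationaryPointDatabase(kappa=5)
            db.add_minimum(0.0)
            db.add_minimum(gap)
            dense = temperature_grid(0.01, 1.5, 50_000)
            locs.append(dense[np.argmax(heat_capacity_curve(db, dense).cv)])
        assert locs[0] < locs[1] < locs[2]
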