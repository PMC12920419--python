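"""Estimation: SSE and likelihood fits, nested variants, goodness of fit."""

import numpy as np
import pytest

from frocfit import (
    ConfidenceCounts,
    FitConfig,
    FrocPoints,
    ItemClass,
    MixtureParams,
    RatingScale,
    build_froc,
    fit_constrained,
    fit_mle,
    fit_sse,
    goodness_of_fit,
    grid_search_sse,
    predicted_froc,
    simulate_condition,
)


def _counts_from_probs(probs, n, item_class, scale):
    return ConfidenceCounts(item_class, np.round(np.asarray(probs) * n), scale)


class TestFitSse:
    def test_noiseless_round_trip(self, criteria, fast_config):
        truth = MixtureParams(r_false=0.2, r_reject=0.25, d_prime=1.0)
        froc = predicted_froc(truth, criteria)
        res = fit_sse(froc, fast_config)
        assert res.converged
        assert res.objective <= 1e-8
        assert res.params.r_false == pytest.approx(truth.r_false, abs=1e-3)
        assert res.params.r_reject == pytest.approx(truth.r_reject, abs=1e-3)
        assert res.params.d_prime == pytest.approx(truth.d_prime, abs=1e-3)
        np.testing.assert_allclose(
            res.criteria.thresholds, criteria.thresholds, atol=1e-3
        )

    def test_chance_data_yields_null_parameters(self, fast_config):
        froc = FrocPoints(
            x=np.array([0.1, 0.3, 0.5, 0.7, 0.9]),
            y=np.array([0.1, 0.3, 0.5, 0.7, 0.9]),
        )
        res = fit_sse(froc, fast_config)
        assert res.params.d_prime <= 1e-3
        assert res.params.r_false <= 1e-3
        assert res.params.r_reject <= 1e-3

    def test_determinism_bit_identical(self, criteria):
        lure, new = simulate_condition(
            MixtureParams(0.1, 0.2, 0.8), criteria, 500, 500, seed=5
        )
        froc = build_froc(lure, new)
        cfg = FitConfig(n_starts=4, seed=11)
        r1, r2 = fit_sse(froc, cfg), fit_sse(froc, cfg)
        assert r1.params == r2.params
        assert r1.objective == r2.objective
        assert np.array_equal(r1.criteria.thresholds, r2.criteria.thresholds)
        assert np.array_equal(r1.per_point_residuals, r2.per_point_residuals)

    def test_degenerate_identical_points_flagged(self, fast_config):
        froc = FrocPoints(x=np.full(5, 0.4), y=np.full(5, 0.4))
        res = fit_sse(froc, fast_config)
        assert not res.converged

    def test_too_few_points_rejected(self, fast_config):
        froc = FrocPoints(x=np.array([0.2]), y=np.array([0.6]))
        with pytest.raises(ValueError):
            fit_sse(froc, fast_config)

    def test_small_sample_warning(self, criteria, fast_config):
        lure, new = simulate_condition(
            MixtureParams(0.1, 0.1, 1.0), criteria, 30, 30, seed=1
        )
        with pytest.warns(UserWarning, match="60"):
            fit_sse(build_froc(lure, new), fast_config)

    def test_estimates_respect_bounds(self, criteria):
        rng = np.random.default_rng(3)
        for seed in range(5):
            lure, new = simulate_condition(
                MixtureParams(
                    r_false=rng.uniform(0, 0.4),
                    r_reject=rng.uniform(0, 0.4),
                    d_prime=rng.uniform(0, 2),
                ),
                criteria, 300, 300, seed=seed,
            )
            res = fit_sse(build_froc(lure, new), FitConfig(n_starts=3, seed=seed))
            p = res.params
            assert 0 <= p.r_false <= 1 and 0 <= p.r_reject <= 1
            assert p.r_false + p.r_reject <= 1 + 1e-12
            assert p.d_prime >= 0
            assert np.all(np.diff(res.criteria.thresholds) > 0)


class TestOracleDominance:
    def test_optimizer_beats_coarse_grid(self, criteria):
        """The continuous fit can never do worse than an exhaustive
        profile-grid search over the process parameters."""
        rng = np.random.default_rng(2024)
        cfg = FitConfig(n_starts=10, seed=0)
        for seed in range(3):
            truth = MixtureParams(
                r_false=rng.uniform(0, 0.4),
                r_reject=rng.uniform(0, 0.4),
                d_prime=rng.uniform(0.2, 2.0),
            )
            lure, new = simulate_condition(truth, criteria, 1000, 1000, seed=seed)
            froc = build_froc(lure, new)
            fit = fit_sse(froc, cfg)
            oracle = grid_search_sse(froc)
            assert fit.objective <= oracle.objective + 1e-12


class TestFitMle:
    def test_large_n_consistency(self, criteria):
        truth = MixtureParams(r_false=0.2, r_reject=0.3, d_prime=0.8)
        lure, new = simulate_condition(truth, criteria, 100_000, 100_000, seed=11)
        res = fit_mle(lure, new, FitConfig(method="mle", n_starts=5, seed=0))
        assert res.params.r_false == pytest.approx(truth.r_false, abs=0.02)
        assert res.params.r_reject == pytest.approx(truth.r_reject, abs=0.02)
        assert res.params.d_prime == pytest.approx(truth.d_prime, abs=0.02)
        assert res.information_criteria is not None
        assert res.information_criteria["aic"] > 0

    def test_degenerate_separation_hits_boundary(self, scale6):
        lure = ConfidenceCounts(ItemClass.LURE, [0, 0, 0, 0, 0, 200], scale6)
        new = ConfidenceCounts(ItemClass.NEW, [200, 0, 0, 0, 0, 0], scale6)
        res = fit_mle(lure, new, FitConfig(method="mle", n_starts=3, seed=0))
        assert res.params.r_false > 0.9
        assert not res.converged

    def test_agrees_with_sse_on_noiseless_counts(self, criteria, scale6):
        truth = MixtureParams(r_false=0.2, r_reject=0.3, d_prime=0.8)
        from frocfit import bin_probabilities

        bp = bin_probabilities(truth, criteria)
        lure = _counts_from_probs(bp.lure, 1_000_000, ItemClass.LURE, scale6)
        new = _counts_from_probs(bp.new, 1_000_000, ItemClass.NEW, scale6)
        cfg_m = FitConfig(method="mle", n_starts=5, seed=0)
        cfg_s = FitConfig(n_starts=5, seed=0)
        m = fit_mle(lure, new, cfg_m)
        s = fit_sse(build_froc(lure, new), cfg_s)
        for name in ("r_false", "r_reject", "d_prime"):
            assert getattr(m.params, name) == pytest.approx(
                getattr(s.params, name), abs=0.01
            )


class TestConstrainedFits:
    def test_evsd_constrained_recovers_d_prime(self, criteria):
        truth = MixtureParams(d_prime=1.0)
        froc = predicted_froc(truth, criteria)
        cfg = FitConfig(n_starts=5, seed=0, fixed={"r_false": 0.0, "r_reject": 0.0})
        res = fit_constrained(froc, cfg)
        assert res.params.d_prime == pytest.approx(1.0, abs=1e-3)
        assert res.params.r_false == 0.0 and res.params.r_reject == 0.0

    def test_linear_two_threshold_closed_form(self):
        """With d' pinned at 0 the model ROC is the line
        y = R_f + (1 - R_f - R_r) x, so a linear fROC identifies
        R_f from the intercept and R_r from the slope."""
        x = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        froc = FrocPoints(x=x, y=0.1 + 0.8 * x)
        cfg = FitConfig(n_starts=10, seed=0, fixed={"d_prime": 0.0})
        res = fit_constrained(froc, cfg)
        assert res.params.r_false == pytest.approx(0.1, abs=1e-3)
        assert res.params.r_reject == pytest.approx(0.1, abs=1e-3)

    def test_nesting_full_fit_dominates_constrained(self, criteria):
        lure, new = simulate_condition(
            MixtureParams(0.15, 0.2, 0.9), criteria, 2000, 2000, seed=4
        )
        froc = build_froc(lure, new)
        full = fit_sse(froc, FitConfig(n_starts=10, seed=0))
        for fixed in (
            {"r_reject": 0.0},
            {"r_false": 0.0},
            {"r_false": 0.0, "r_reject": 0.0},
            {"d_prime": 0.0},
        ):
            nested = fit_constrained(froc, FitConfig(n_starts=10, seed=0, fixed=fixed))
            assert full.objective <= nested.objective + 1e-9

    def test_uvsd_variant_frees_variance_ratio(self, criteria):
        truth = MixtureParams(d_prime=1.2, variance_ratio=1.4)
        froc = predicted_froc(truth, criteria)
        cfg = FitConfig(
            n_starts=10, seed=0,
            fixed={"r_false": 0.0, "r_reject": 0.0},
            free_variance_ratio=True,
        )
        res = fit_constrained(froc, cfg)
        assert res.params.variance_ratio == pytest.approx(1.4, abs=0.01)
        assert res.params.d_prime == pytest.approx(1.2, abs=0.01)

    def test_infeasible_fixed_values_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(fixed={"r_false": 0.7, "r_reject": 0.6})
        with pytest.raises(ValueError):
            FitConfig(fixed={"d_prime": -1.0})


class TestGoodnessOfFit:
    def test_perfect_fit_has_zero_sse(self, criteria, fast_config):
        truth = MixtureParams(0.2, 0.25, 1.0)
        froc = predicted_froc(truth, criteria)
        res = fit_sse(froc, fast_config)
        report = goodness_of_fit(res, froc)
        assert report.sse == pytest.approx(0.0, abs=1e-8)

    def test_single_point_offset_arithmetic(self, criteria, fast_config):
        truth = MixtureParams(0.2, 0.25, 1.0)
        froc = predicted_froc(truth, criteria)
        res = fit_sse(froc, fast_config)
        shifted = FrocPoints(
            x=froc.x + np.array([0.01, 0, 0, 0, 0]),
            y=froc.y + np.array([0.02, 0, 0, 0, 0]),
        )
        report = goodness_of_fit(res, shifted)
        assert report.sse == pytest.approx(0.0005, abs=1e-6)

    def test_report_matches_optimizer_objective(self, criteria):
        lure, new = simulate_condition(
            MixtureParams(0.1, 0.3, 0.7), criteria, 800, 800, seed=9
        )
        froc = build_froc(lure, new)
        res = fit_sse(froc, FitConfig(n_starts=5, seed=0))
        report = goodness_of_fit(res, froc)
        assert report.sse == pytest.approx(res.objective, abs=1e-12)

    def test_mismatched_lengths_rejected(self, criteria, fast_config):
        froc = predicted_froc(MixtureParams(0.2, 0.25, 1.0), criteria)
        res = fit_sse(froc, fast_config)
        other = FrocPoints(x=np.array([0.2, 0.4]), y=np.array([0.3, 0.5]))
        with pytest.raises(ValueError):
            goodness_of_fit(res, other)


class TestSerialization:
    def test_result_round_trips_to_json_and_csv_row(self, criteria, fast_config):
        froc = predicted_froc(MixtureParams(0.2, 0.25, 1.0), criteria)
        res = fit_sse(froc, fast_config)
        import json

        payload = json.loads(res.to_json())
        assert set(payload) >= {
            "r_false", "r_reject", "d_prime", "thresholds", "objective",
            "converged", "method",
        }
        row = res.to_csv_row(study_id="demo", condition="a")
        assert row["study_id"] == "demo"
        assert row["r_false"] == pytest.approx(0.2, abs=1e-3)
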