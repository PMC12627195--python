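"""Hierarchical Bayesian DoG fitting: diagnostics, recovery, oracle checks."""

import numpy as np
import pandas as pd
import pytest

import serialbias as sb
from tests.conftest import PAPER_BINS


def cell_table(values_by_cell, value_col="error_deg"):
    """Build a tidy summary table from {(participant, report[, t]): y array}."""
    rows = []
    for key, y in values_by_cell.items():
        for b, v in zip(PAPER_BINS, y):
            rec = {"participant": key[0], "report_type": key[1],
                   "bin_center": b, value_col: v}
            if len(key) == 3:
                rec["time_point"] = key[2]
            rows.append(rec)
    return pd.DataFrame(rows)


class TestRhat:
    def test_converged_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(0, 1, size=(2, 20_000))
        assert sb.compute_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_large(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert sb.compute_rhat(chains) > 1.5

    def test_constant_chains_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(sb.compute_rhat(np.ones((2, 100))))

    def test_matches_arviz_split_rhat(self):
        import arviz as az

        rng = np.random.default_rng(2)
        chains = np.cumsum(rng.normal(0, 1, size=(4, 500)), axis=1) * 0.05 + rng.normal(
            0, 1, size=(4, 500)
        )
        ours = sb.compute_rhat(chains)
        theirs = float(np.asarray(az.rhat(az.convert_to_dataset(chains[:, :, None]),
                                          method="split").x).ravel()[0])
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            sb.compute_rhat(np.ones(10))


class TestHdi:
    def test_normal_draws(self):
        rng = np.random.default_rng(3)
        lo, hi = sb.compute_hdi(rng.normal(0, 1, 100_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_point_mass(self):
        lo, hi = sb.compute_hdi(np.full(500, 2.5), 0.95)
        assert (lo, hi) == (2.5, 2.5)

    def test_uniform_width(self):
        rng = np.random.default_rng(4)
        lo, hi = sb.compute_hdi(rng.uniform(0, 1, 200_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_matches_arviz(self):
        import arviz as az

        rng = np.random.default_rng(5)
        draws = rng.gamma(2.0, 1.0, 50_000)
        ours = sb.compute_hdi(draws, 0.95)
        theirs = az.hdi(draws, hdi_prob=0.95)
        assert ours[0] == pytest.approx(theirs[0], abs=0.02)
        assert ours[1] == pytest.approx(theirs[1], abs=0.02)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            sb.compute_hdi(np.arange(50))


class TestSpecDefaults:
    def test_three_level_defaults(self):
        spec = sb.HierarchicalSpec(levels=3)
        assert spec.n_warmup == spec.n_samples == 12_000

    def test_four_level_defaults(self):
        spec = sb.HierarchicalSpec(levels=4)
        assert spec.n_warmup == spec.n_samples == 2_000

    def test_validation(self):
        with pytest.raises(ValueError):
            sb.HierarchicalSpec(levels=2)
        with pytest.raises(ValueError):
            sb.HierarchicalSpec(share_w="everything")


class TestOracleEquivalence:
    def test_single_cell_matches_least_squares(self):
        rng = np.random.default_rng(3)
        y = sb.dog(PAPER_BINS, 3.0, 0.022, 0.5) + rng.normal(0, 0.05, 10)
        table = cell_table({(0, "consolidation"): y})
        params, _ = sb.fit_dog_leastsquares(PAPER_BINS, y)
        post, _ = sb.fit_hbm3(table, sb.HierarchicalSpec(
            levels=3, n_chains=4, n_warmup=2000, n_samples=2000, seed=5))
        for name, ref in (("alpha", params.alpha), ("w", params.w),
                          ("beta", params.beta)):
            d = post.draws[name][:, 0, 0]
            assert abs(d.mean() - ref) < 2 * d.std()


class TestFits:
    def test_null_data_inconclusive(self):
        rng = np.random.default_rng(6)
        table = cell_table({
            (p, rt): rng.normal(0, 0.1, 10)
            for p in range(4) for rt in sb.REPORT_TYPES
        })
        post, diag = sb.fit_hbm3(table, sb.HierarchicalSpec(
            levels=3, n_chains=2, n_warmup=600, n_samples=600, seed=7))
        summary = sb.posterior_summary(post, diag)
        assert (summary.verdict == "inconclusive").all()

    def test_reproducible_draws(self):
        rng = np.random.default_rng(8)
        table = cell_table({
            (p, rt): sb.dog(PAPER_BINS, 2.0, 0.02, 0) + rng.normal(0, 0.5, 10)
            for p in range(2) for rt in ("perceptual", "retrieval")
        })
        spec = sb.HierarchicalSpec(levels=3, n_chains=2, n_warmup=150,
                                   n_samples=200, seed=9)
        p1, _ = sb.fit_hbm3(table, spec)
        p2, _ = sb.fit_hbm3(table, spec)
        for name in ("alpha", "w", "beta"):
            np.testing.assert_array_equal(p1.draws[name], p2.draws[name])

    def test_four_level_shape_and_time_profile(self):
        rng = np.random.default_rng(10)
        nodes = np.round(np.arange(1, 21) * 0.05, 2)
        # amplitude ramps from negative to positive over movement time
        table = cell_table({
            (p, "consolidation", t): sb.dog(PAPER_BINS, -2.0 + 6.0 * t, 0.02, 0)
            + rng.normal(0, 0.3, 10)
            for p in range(3) for t in nodes
        }, value_col="mean_dev")
        post, diag = sb.fit_hbm4(table, sb.HierarchicalSpec(
            levels=4, n_chains=2, n_warmup=500, n_samples=500, seed=11))
        assert post.draws["alpha"].shape == (500, 3, 1, 20)
        summary = sb.posterior_summary(post, diag)
        early = summary[summary.time_point == 0.1].iloc[0]
        late = summary[summary.time_point == 0.9].iloc[0]
        assert early["mean"] < 0 < late["mean"]
        assert early.verdict == "credibly negative"
        assert late.verdict == "credibly positive"

    def test_estimator_interface(self):
        rng = np.random.default_rng(12)
        table = cell_table({
            (p, rt): sb.dog(PAPER_BINS, 3.0, 0.02, 0) + rng.normal(0, 0.5, 10)
            for p in range(2) for rt in ("perceptual", "retrieval")
        })
        est = sb.HierarchicalDoGModel(n_chains=2, n_warmup=150, n_samples=200,
                                      random_state=1)
        est.fit(table)
        assert hasattr(est, "posterior_") and hasattr(est, "summary_")
        assert est.get_params()["n_chains"] == 2
        alphas = sb.participant_alpha_means(est.posterior_)
        assert alphas.shape == (2, 2)


class TestConvergenceDefaultScale:
    def test_rhat_close_to_one_on_default_synthetic_data(self):
        """Population-level split R-hat <= 1.05 at the full study scale."""
        ds = sb.simulate_experiment(sb.SimConfig(include_trajectories=False, seed=0))
        summaries = sb.prepare_condition_summaries(ds.trials)
        post, diag = sb.fit_hbm3(summaries, sb.HierarchicalSpec(levels=3, seed=1))
        assert diag.max_rhat <= 1.05
        assert diag.converged
        # and the sign pattern of the generating regimes is recovered
        verdicts = sb.posterior_summary(post, diag).set_index("report_type").verdict
        assert verdicts["perceptual"] == "credibly negative"
        assert verdicts["consolidation"] == "credibly positive"
        assert verdicts["retrieval"] == "credibly positive"
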