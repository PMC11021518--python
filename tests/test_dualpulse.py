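import math

import numpy as np
import pandas as pd
import pytest

from pulsevar import dualpulse, experiments, simcell


class TestOLSFit:
    def test_closed_form_example(self):
        fit = dualpulse.ols_fit([1, 2, 3], [2, 4, 9])
        assert fit.slope == pytest.approx(3.5)
        assert fit.intercept == pytest.approx(-2.0)
        assert fit.r2 == pytest.approx(1 - 1.5 / 26)  # SSE=1.5, SST=26

    def test_exact_line_gives_r2_one(self):
        x = np.linspace(0, 5, 10)
        fit = dualpulse.ols_fit(x, 3 * x + 1)
        assert fit.r2 == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero_r2(self, rng):
        x = rng.normal(size=10000)
        y = rng.normal(size=10000)
        assert dualpulse.ols_fit(x, y).r2 < 0.01

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        x = rng.lognormal(size=200)
        y = 2.0 * x + rng.normal(scale=0.5, size=200)
        fit = dualpulse.ols_fit(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(ref.params[1], rel=1e-9)
        assert fit.intercept == pytest.approx(ref.params[0], rel=1e-9)
        assert fit.r2 == pytest.approx(ref.rsquared, rel=1e-9)

    def test_degenerate_x_errors(self):
        with pytest.raises(ValueError, match="degenerate|variance"):
            dualpulse.ols_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestFitDecorrelation:
    def _curve(self, tau, beta, r2_0, intervals):
        t = np.asarray(intervals, dtype=float)
        return pd.DataFrame(
            {"interval_min": t, "r2": r2_0 * np.exp(-2 * (t / tau) ** beta)}
        )

    def test_noiseless_round_trip(self):
        curve = self._curve(50.8, 1.27, 0.85, range(0, 111, 10))
        fit = dualpulse.fit_decorrelation(curve)
        assert fit.tau_hat_min == pytest.approx(50.8, rel=0.01)
        assert fit.beta_hat == pytest.approx(1.27, rel=0.01)
        assert fit.r2_0 == pytest.approx(0.85, rel=0.01)

    def test_three_reported_points_match_closed_form(self):
        curve = pd.DataFrame(
            {"interval_min": [0.0, 20.0, 50.0], "r2": [0.85, 0.46, 0.12]}
        )
        fit = dualpulse.fit_decorrelation(curve)
        tau, beta = simcell.calibrate_kernel_closed_form()
        assert fit.tau_hat_min == pytest.approx(tau, rel=0.01)
        assert fit.beta_hat == pytest.approx(beta, abs=0.02)

    def test_half_decay_consistent_with_parameters(self):
        curve = self._curve(40.0, 1.1, 0.8, range(0, 101, 10))
        fit = dualpulse.fit_decorrelation(curve)
        model_at_half = fit.r2_0 * math.exp(
            -2 * (fit.half_decay_min / fit.tau_hat_min) ** fit.beta_hat
        )
        assert model_at_half == pytest.approx(fit.r2_0 / 2, rel=1e-6)

    def test_requires_interval_zero(self):
        with pytest.raises(ValueError):
            dualpulse.fit_decorrelation(
                pd.DataFrame({"interval_min": [10.0, 20, 30], "r2": [0.5, 0.3, 0.2]})
            )


class TestRankGroups:
    def _table(self, values):
        return pd.DataFrame(
            {
                "cell_id": [f"c{i:03d}" for i in range(len(values))],
                "signal_HPG_norm": values,
            }
        )

    def test_even_split(self, rng):
        t = self._table(rng.random(100))
        groups = dualpulse.rank_groups(t)
        assert groups.value_counts().eq(10).all()

    def test_uneven_split_extra_in_lowest_group(self, rng):
        t = self._table(rng.random(101))
        sizes = dualpulse.rank_groups(t).value_counts().sort_index()
        assert sizes.loc[1] == 11
        assert (sizes.loc[2:] == 10).all()

    def test_ordering_of_group_means(self, rng):
        t = self._table(rng.random(200))
        g = dualpulse.rank_groups(t)
        means = t.groupby(g)["signal_HPG_norm"].mean()
        assert means.loc[10] > means.loc[1]

    def test_permutation_invariance(self, rng):
        t = self._table(rng.random(97))
        g1 = dualpulse.rank_groups(t)
        shuffled = t.sample(frac=1.0, random_state=1)
        g2 = dualpulse.rank_groups(shuffled)
        merged = pd.DataFrame({"a": g1, "cell_id": t.cell_id}).merge(
            pd.DataFrame({"b": g2, "cell_id": shuffled.cell_id}), on="cell_id"
        )
        assert (merged.a == merged.b).all()

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError):
            dualpulse.rank_groups(self._table([1.0, 2.0]), n_groups=10)


@pytest.fixture(scope="module")
def samples():
    return experiments.dual_pulse_samples([0, 20, 50], n_cells_per_interval=4000, seed=17)


class TestPipeline:
    def test_r2_curve_decreases_with_interval(self, samples):
        curve = dualpulse.r2_decay_curve(samples)
        r2 = curve.sort_values("interval_min")["r2"].to_numpy()
        assert np.all(np.diff(r2) < 0)

    def test_simultaneous_pulse_preserves_ranking(self, samples):
        traj, pop, _ = dualpulse.group_trajectories(samples)
        at0 = traj[traj.interval_min == 0].set_index("group")["mean_norm_aha"]
        assert at0.loc[10] > 1.0 > at0.loc[1]

    def test_missing_channel_errors(self, samples):
        broken = {k: v.drop(columns=["signal_AHA_norm"]) for k, v in samples.items()}
        with pytest.raises(ValueError, match="signal_AHA_norm"):
            dualpulse.r2_decay_curve(broken)


class TestGroupTrajectories:
    def test_convergence_rule_on_fabricated_decay(self, rng):
        """Deviations decaying geometrically cross the one-third threshold at
        the first interval where the ratio drops below 1/3."""
        samples = {}
        for i, interval in enumerate([0.0, 20.0, 40.0, 60.0]):
            factor = 0.5**i  # 1, 1/2, 1/4 (<1/3 at 40), ...
            base = np.linspace(-0.5, 0.5, 100) * factor + 1.0
            samples[interval] = pd.DataFrame(
                {
                    "cell_id": [f"c{j:03d}" for j in range(100)],
                    "signal_HPG_norm": np.linspace(0, 1, 100),
                    "signal_AHA_norm": base,
                }
            )
        _, _, conv = dualpulse.group_trajectories(samples)
        assert conv[1] == 40.0
        assert conv[10] == 40.0
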