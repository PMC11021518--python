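import math

import numpy as np
import pandas as pd
import pytest

from pulsevar import simcell
from pulsevar.params import (
    CalibrationError,
    MeasurementParams,
    ParameterError,
    PulseScheme,
    RateProcessParams,
    StrainSpec,
)


class TestCorrelationKernel:
    def test_lag_zero_is_one(self):
        p = RateProcessParams(tau_min=50.0, beta=1.3)
        assert simcell.correlation_kernel(p, 0.0) == 1.0

    def test_exponential_special_case(self):
        p = RateProcessParams(tau_min=65.2, beta=1.0)
        assert simcell.correlation_kernel(p, 40.0) == pytest.approx(
            math.exp(-40 / 65.2)
        )

    def test_calibrated_kernel_at_20min(self):
        tau, beta = simcell.calibrate_kernel_closed_form()
        p = RateProcessParams(tau_min=tau, beta=beta)
        # two-point solve through sqrt(0.46/0.85) at 20 and sqrt(0.12/0.85) at 50
        assert simcell.correlation_kernel(p, 20.0) == pytest.approx(0.7356, abs=1e-3)

    def test_strictly_decreasing(self):
        p = RateProcessParams(tau_min=30.0, beta=1.5)
        dts = np.linspace(0, 200, 100)
        vals = simcell.correlation_kernel(p, dts)
        assert np.all(np.diff(vals) < 0)

    def test_negative_lag_rejected(self):
        with pytest.raises(ParameterError):
            simcell.correlation_kernel(RateProcessParams(), -1.0)

    @pytest.mark.parametrize("bad", [dict(tau_min=-1.0), dict(beta=2.5), dict(beta=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            RateProcessParams(**bad)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 1.27, 2.0])
    def test_kernel_positive_definite_on_256_grid(self, beta):
        grid = np.arange(256.0)
        chol = simcell._cholesky_corr(grid, tau=50.0, beta=beta)
        assert chol.shape == (256, 256)


class TestCalibration:
    def test_closed_form_matches_two_point_solve(self):
        tau, beta = simcell.calibrate_kernel_closed_form()
        assert tau == pytest.approx(50.85, abs=0.05)
        assert beta == pytest.approx(1.2655, abs=0.005)

    def test_exponential_anchors_recover_ou(self):
        tau_star = 40.0
        anchors = {
            0.0: 0.85,
            20.0: 0.85 * math.exp(-2 * 20 / tau_star),
            50.0: 0.85 * math.exp(-2 * 50 / tau_star),
        }
        tau, beta = simcell.calibrate_kernel_closed_form(anchors)
        assert beta == pytest.approx(1.0, abs=1e-9)
        assert tau == pytest.approx(tau_star, rel=1e-9)

    def test_lognormal_cv_identity(self):
        # total log-SD implied by the CV target
        assert math.sqrt(math.log(1 + 0.31**2)) == pytest.approx(0.3029, abs=1e-4)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(CalibrationError):
            simcell.calibrate_kernel_closed_form({0.0: 0.85, 20.0: 0.9, 50.0: 0.12})

    def test_default_calibration_is_plausible(self, calibration):
        rate, meas = calibration
        assert 0.2 < rate.s < 0.4
        assert 0 <= meas.sigma_meas < 0.3
        assert 30 < rate.tau_min < 70
        assert 0.8 < rate.beta < 1.6


class TestSimulateCells:
    def test_noise_free_limit_signals_are_deterministic_in_length(self, growth):
        """With vanishing rate fluctuation, measurement noise, and background
        spread, the signal is an exact function of cell age/length."""
        rate = RateProcessParams(mean_rate=100.0, s=1e-9, tau_min=50.0, beta=1.0)
        meas = MeasurementParams(sigma_meas=0.0, background_median=10.0, background_log_sd=0.0)
        pulse = PulseScheme("HPG", 0.0, 5.0)
        cells = simcell.simulate_cells(rate, growth, meas, [pulse], 200, seed=1)
        T = growth.generation_min
        lb, ld = growth.birth_length_um, growth.division_length_um
        a0 = (cells["length_um"] - lb) / (ld - lb) * T - pulse.duration_min
        expected = (
            rate.mean_rate
            * pulse.duration_min
            * (lb + (ld - lb) * (a0 + pulse.duration_min / 2) / T)
            + meas.background_median
        )
        assert np.allclose(cells["signal_HPG"], expected, rtol=1e-6)

    def test_lag_correlation_recovery(self):
        """Empirical log-rate correlation at a chosen lag matches the kernel."""
        tau, beta = 48.0, 1.2
        grid = np.arange(0.0, 61.0)
        chol = simcell._cholesky_corr(grid, tau, beta)
        rng = np.random.default_rng(5)
        x = rng.standard_normal((12000, len(grid))) @ chol.T
        for lag in (10, 20, 50):
            emp = np.corrcoef(x[:, 0], x[:, lag])[0, 1]
            assert emp == pytest.approx(math.exp(-((lag / tau) ** beta)), abs=0.03)

    def test_time_averaging_shrinks_qcd(self, calibration):
        rate, _ = calibration
        tbl = simcell.simulate_time_averaged_rates(rate, [10, 60, 180], 4000, seed=2)
        from pulsevar import varstats

        q10 = varstats.qcd(tbl["T10"])
        q60 = varstats.qcd(tbl["T60"])
        q180 = varstats.qcd(tbl["T180"])
        assert q10 > q60 > q180

    def test_seed_determinism(self, calibration, growth):
        rate, meas = calibration
        kwargs = dict(pulses=[PulseScheme("HPG", 0, 5)], n_cells=100, seed=11)
        a = simcell.simulate_cells(rate, growth, meas, **kwargs)
        b = simcell.simulate_cells(rate, growth, meas, **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_table_written_byte_identically(self, tmp_path, calibration, growth):
        rate, meas = calibration
        df = simcell.simulate_cells(
            rate, growth, meas, [PulseScheme("HPG", 0, 5)], 50, seed=3
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        simcell.write_table(df, p1)
        simcell.write_table(df, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_pulse_beyond_horizon_errors(self, calibration, growth):
        rate, meas = calibration
        with pytest.raises(ParameterError, match="horizon"):
            simcell.simulate_cells(
                rate, growth, meas, [PulseScheme("HPG", 0, 30)], 10,
                horizon_min=20.0,
            )

    def test_nonpositive_n_cells_errors(self, calibration, growth):
        rate, meas = calibration
        with pytest.raises(ParameterError):
            simcell.simulate_cells(rate, growth, meas, [PulseScheme("HPG", 0, 5)], 0)

    def test_background_rows_carry_background_only(self, small_sample, calibration):
        _, meas = calibration
        bg = small_sample[small_sample.is_background]
        assert len(bg) == 400
        # background-only draws sit at the background scale, well below signal
        assert bg["signal_HPG"].median() == pytest.approx(
            meas.background_median, rel=0.1
        )

    def test_binucleate_population_fraction_matches_age_distribution(
        self, small_sample, growth
    ):
        # under the steady-state age density 2^(-a/T), the mass in the final
        # fraction f of the cycle is 2*(2**(f-1) - 1/2), below f itself
        f = growth.binucleate_fraction
        expected = 2 * (2 ** (f - 1) - 0.5)
        frac = (small_sample["n_nuclei"] == 2).mean()
        assert frac == pytest.approx(expected, abs=0.02)


class TestScreenDataset:
    def _args(self, calibration, growth):
        rate, meas = calibration
        strains = [StrainSpec("WT", 1.0, 2), StrainSpec("mutA", 1.5, 1)]
        return strains, rate, growth, meas

    def test_determinism_and_counter_scheme(self, calibration, growth):
        strains, rate, g, meas = self._args(calibration, growth)
        a = simcell.simulate_screen_dataset(strains, rate, g, meas, n_cells_per_sample=50, seed=4)
        b = simcell.simulate_screen_dataset(strains, rate, g, meas, n_cells_per_sample=50, seed=4)
        pd.testing.assert_frame_equal(a, b)
        # adding a strain must not perturb existing samples
        more = strains + [StrainSpec("mutB", 0.6, 1)]
        c = simcell.simulate_screen_dataset(more, rate, g, meas, n_cells_per_sample=50, seed=4)
        pd.testing.assert_frame_equal(
            c[c.strain_id.isin(["WT", "mutA"])].reset_index(drop=True), a
        )

    def test_duplicate_strain_rejected(self, calibration, growth):
        strains, rate, g, meas = self._args(calibration, growth)
        with pytest.raises(ParameterError, match="duplicate"):
            simcell.simulate_screen_dataset(
                strains + [StrainSpec("WT", 1.0, 1)], rate, g, meas, seed=0
            )

    def test_missing_wildtype_rejected(self, calibration, growth):
        _, rate, g, meas = self._args(calibration, growth)
        with pytest.raises(ParameterError, match="wild-type"):
            simcell.simulate_screen_dataset(
                [StrainSpec("mutA", 1.5, 3)], rate, g, meas, seed=0
            )


class TestRenderImages:
    def test_single_cell_conservation(self, calibration):
        _, meas = calibration
        cell = pd.DataFrame(
            [{"cell_id": "a", "length_um": 9.0, "n_nuclei": 1, "signal_HPG": 10000.0}]
        )
        img, cm, _ = simcell.render_images(cell, meas)
        assert int(img[cm == 1].sum()) == 10000
        assert img.dtype == np.uint16

    def test_feret_matches_nominal_length(self, calibration):
        from pulsevar import quant

        _, meas = calibration
        cell = pd.DataFrame(
            [{"cell_id": "a", "length_um": 10.0, "n_nuclei": 1, "signal_HPG": 100.0}]
        )
        _, cm, _ = simcell.render_images(cell, meas)
        assert quant.feret_diameter(cm == 1) == pytest.approx(153.609, abs=1.0)

    def test_binucleate_cell_has_two_dna_components(self, calibration):
        _, meas = calibration
        cell = pd.DataFrame(
            [{"cell_id": "a", "length_um": 12.0, "n_nuclei": 2, "signal_HPG": 100.0}]
        )
        _, cm, dm = simcell.render_images(cell, meas)
        labels = np.unique(dm[dm > 0])
        assert len(labels) == 2
        assert np.all(cm[dm > 0] == 1)

    def test_canvas_overflow_reports_cells(self, calibration):
        _, meas = calibration
        cell = pd.DataFrame(
            [{"cell_id": "big", "length_um": 14.0, "n_nuclei": 1, "signal_HPG": 1.0}]
        )
        with pytest.raises(ParameterError, match="big|canvas"):
            simcell.render_images(cell, meas, shape=(50, 50))
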