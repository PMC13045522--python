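import io

import numpy as np
import pandas as pd
import pytest

from valvejet.rheology import (
    FlowCurve,
    ModuliSweep,
    apparent_viscosity,
    fit_power_law,
    load_flow_curve,
    summarize_moduli,
)
from valvejet.synth import SynthSpec, gen_flow_curve


def _noiseless_curve(K, n, count=20):
    gdot = np.geomspace(0.1, 1000, count)
    return FlowCurve(shear_rates=gdot, viscosities=K * gdot ** (n - 1))


class TestLoadFlowCurve:
    def _csv(self, df):
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return buf

    def test_well_formed_table_passes_through(self):
        gdot = np.linspace(1, 30, 30)
        df = pd.DataFrame({"shear_rate_1_per_s": gdot, "viscosity_Pa_s": 0.01 / gdot**0.5})
        curve = load_flow_curve(self._csv(df))
        assert len(curve) == 30
        assert curve.n_dropped == 0

    def test_zero_shear_row_dropped_and_counted(self):
        df = pd.DataFrame(
            {"shear_rate_1_per_s": [0.0, 1, 2, 3, 4, 5], "viscosity_Pa_s": [1] * 6}
        )
        curve = load_flow_curve(self._csv(df))
        assert len(curve) == 5
        assert curve.n_dropped == 1

    def test_missing_viscosity_column_named(self):
        df = pd.DataFrame({"shear_rate_1_per_s": [1, 2, 3, 4, 5]})
        with pytest.raises(ValueError, match="viscosity"):
            load_flow_curve(self._csv(df))

    def test_too_few_usable_rows_rejected(self):
        df = pd.DataFrame({"shear_rate_1_per_s": [1, 2, 3], "viscosity_Pa_s": [1, 1, 1]})
        with pytest.raises(ValueError, match="usable rows"):
            load_flow_curve(self._csv(df))

    def test_custom_column_map(self):
        df = pd.DataFrame({"gdot": [1, 2, 3, 4, 5], "mu": [1, 1, 1, 1, 1]})
        curve = load_flow_curve(
            self._csv(df), column_map={"shear_rate": "gdot", "viscosity": "mu"}
        )
        assert len(curve) == 5


class TestFitPowerLaw:
    @pytest.mark.parametrize("n_true", [0.2, 0.5, 0.8, 1.0])
    def test_noiseless_recovery(self, n_true):
        """Noiseless power-law data returns the generating (K, n) to 1e-6."""
        fit = fit_power_law(_noiseless_curve(2.0, n_true))
        assert fit.K == pytest.approx(2.0, rel=1e-6)
        assert fit.n == pytest.approx(n_true, rel=1e-6)
        assert fit.converged

    def test_newtonian_identity(self):
        """Constant viscosity fits to n = 1, K = that viscosity."""
        gdot = np.geomspace(0.1, 1000, 20)
        fit = fit_power_law(FlowCurve(shear_rates=gdot, viscosities=np.full(20, 0.005)))
        assert fit.n == pytest.approx(1.0, abs=1e-9)
        assert fit.K == pytest.approx(0.005, rel=1e-9)

    def test_weighted_fit_matches_grid_search_oracle(self):
        """Inverse-square-weighted optimum agrees with a brute-force grid search.

        Heteroscedastic data (10% multiplicative noise): the damped
        least-squares minimiser of Σ(µᵢ − Kγ̇ᵢ^(n−1))²/µᵢ² must land within
        one grid cell of the exhaustive 200×200 (log K, n) minimum.
        """
        curve = gen_flow_curve(
            0.5, 0.6, spec=SynthSpec(seed=7, noise_model="multiplicative_lognormal",
                                     noise_level=0.10)
        )
        fit = fit_power_law(curve, "inverse_square")

        logK_grid = np.linspace(np.log(0.5) - 0.5, np.log(0.5) + 0.5, 200)
        n_grid = np.linspace(0.4, 0.8, 200)
        gdot, mu = curve.shear_rates, curve.viscosities
        obj = np.empty((200, 200))
        for i, lk in enumerate(logK_grid):
            model = np.exp(lk) * gdot[None, :] ** (n_grid[:, None] - 1)
            obj[i] = np.sum(((mu[None, :] - model) / mu[None, :]) ** 2, axis=1)
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        dK = logK_grid[1] - logK_grid[0]
        dn = n_grid[1] - n_grid[0]
        assert np.log(fit.K) == pytest.approx(logK_grid[i], abs=2 * dK)
        assert fit.n == pytest.approx(n_grid[j], abs=2 * dn)

    def test_stochastic_recovery_median_error_below_2_percent(self):
        """1% multiplicative noise, 30 points, 200 seeds: median |rel err| < 2%."""
        errs_K, errs_n = [], []
        for seed in range(200):
            curve = gen_flow_curve(
                0.05, 0.7,
                spec=SynthSpec(seed=seed, noise_model="multiplicative_lognormal",
                               noise_level=0.01),
            )
            fit = fit_power_law(curve)
            errs_K.append(abs(fit.K / 0.05 - 1))
            errs_n.append(abs(fit.n / 0.7 - 1))
        assert np.median(errs_K) < 0.02
        assert np.median(errs_n) < 0.02

    def test_inverse_square_equals_relative_residual_fit(self):
        """On noiseless data both weightings share the exact minimiser."""
        curve = _noiseless_curve(1.5, 0.4)
        fw = fit_power_law(curve, "inverse_square")
        fu = fit_power_law(curve, "none")
        assert fw.K == pytest.approx(fu.K, rel=1e-5)
        assert fw.n == pytest.approx(fu.n, rel=1e-5)

    def test_unknown_weighting_rejected(self):
        with pytest.raises(ValueError, match="weighting"):
            fit_power_law(_noiseless_curve(1, 0.5), "huber")


class TestApparentViscosity:
    def test_closed_form(self):
        from valvejet.rheology import PowerLawFit

        fit = PowerLawFit(consistency_index=2.0, flow_index=0.5)
        assert apparent_viscosity(fit, 4.0) == pytest.approx(1.0)

    def test_newtonian_floor_irrelevant(self):
        from valvejet.rheology import PowerLawFit

        fit = PowerLawFit(consistency_index=0.005, flow_index=1.0)
        assert apparent_viscosity(fit, 0.0) == pytest.approx(0.005)

    def test_floor_regularises_zero_shear(self):
        from valvejet.rheology import PowerLawFit

        fit = PowerLawFit(consistency_index=2.0, flow_index=0.5)
        assert apparent_viscosity(fit, 0.0, floor=1e-2) == pytest.approx(20.0)

    @pytest.mark.parametrize("n,monotone", [(0.5, -1), (1.0, 0)])
    def test_monotone_in_shear_rate(self, n, monotone):
        """µ(γ̇) is non-increasing for n < 1 and constant for n = 1."""
        from valvejet.rheology import PowerLawFit

        fit = PowerLawFit(consistency_index=1.0, flow_index=n)
        gdot = np.geomspace(1e-3, 1e4, 50)
        mu = apparent_viscosity(fit, gdot)
        diffs = np.diff(mu)
        if monotone < 0:
            assert np.all(diffs <= 0)
            assert np.any(diffs < 0)
        else:
            assert np.allclose(diffs, 0)


class TestSummarizeModuli:
    def test_constant_moduli(self):
        sweep = ModuliSweep(
            strains=np.logspace(-3, 0, 10),
            storage_modulus=np.full(10, 10.0),
            loss_modulus=np.full(10, 5.0),
        )
        s = summarize_moduli(sweep, lve_strain_max=0.1)
        assert (s.mean_storage, s.mean_loss) == (10.0, 5.0)
        assert s.tan_delta == pytest.approx(0.5)

    def test_equal_moduli_tan_delta_one(self):
        g = np.linspace(3, 8, 8)
        sweep = ModuliSweep(strains=np.logspace(-3, -1, 8),
                            storage_modulus=g, loss_modulus=g)
        assert summarize_moduli(sweep, 1.0).tan_delta == pytest.approx(1.0)

    def test_window_restricted_to_plateau(self):
        """Plateau-then-decay sweep: LVE window reproduces plateau exactly."""
        strains = np.logspace(-3, 0.5, 20)
        plateau = strains <= 0.01
        g1 = np.where(plateau, 100.0, 100.0 * (0.01 / strains) ** 0.8)
        g2 = np.where(plateau, 20.0, 20.0 * (0.01 / strains) ** 0.4)
        sweep = ModuliSweep(strains=strains, storage_modulus=g1, loss_modulus=g2)
        s = summarize_moduli(sweep, lve_strain_max=0.01)
        assert s.mean_storage == pytest.approx(100.0, rel=1e-9)
        assert s.mean_loss == pytest.approx(20.0, rel=1e-9)

    def test_empty_window_rejected(self):
        sweep = ModuliSweep(strains=np.array([0.1, 0.2, 0.5]),
                            storage_modulus=np.ones(3), loss_modulus=np.ones(3))
        with pytest.raises(ValueError, match="window"):
            summarize_moduli(sweep, lve_strain_max=1e-4)
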