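"""Growth-rate estimation, SCFA ratios and consumption rates."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mucimin.growth import (
    GrowthCurve,
    GrowthDataError,
    GrowthRateConfig,
    MetaboliteTimeSeries,
    consumption_rates,
    estimate_growth_rate,
    read_growth_csv,
    read_hplc_csv,
    scfa_ratio,
    write_growth_csv,
    write_hplc_csv,
)
from mucimin.synth import SimConfig, simulate_fermentation, simulate_growth_curve


def exponential_curve(mu=0.1, od0=0.02, t_end=60.0, step=2.0):
    t = np.arange(0.0, t_end + 1e-9, step)
    return GrowthCurve(times=t, od600=od0 * np.exp(mu * t))


class TestGrowthRate:
    def test_exact_on_pure_exponential(self):
        est = estimate_growth_rate([exponential_curve(mu=0.1)])
        assert est.mu == pytest.approx(0.1, rel=1e-9)
        assert not est.no_growth
        assert est.r_squared == pytest.approx(1.0)

    def test_scale_invariant(self):
        base = exponential_curve(mu=0.08)
        scaled = GrowthCurve(times=base.times, od600=base.od600 * 3.7)
        mu_a = estimate_growth_rate([base]).mu
        mu_b = estimate_growth_rate([scaled]).mu
        assert mu_a == pytest.approx(mu_b, rel=1e-9)

    def test_flat_noisy_curve_flagged_no_growth(self):
        curves = simulate_growth_curve(
            0.0, config=SimConfig(seed=5, noise_cv=0.03, n_replicates=3)
        )
        est = estimate_growth_rate(curves)
        assert est.no_growth and est.mu == 0.0

    @pytest.mark.parametrize("mu,sd", [(0.122, 0.036), (0.056, 0.023),
                                       (0.084, 0.014)])
    def test_recovers_reference_rates_within_reported_sd(self, mu, sd):
        curves = simulate_growth_curve(
            mu, config=SimConfig(seed=11, noise_cv=0.03, n_replicates=3)
        )
        est = estimate_growth_rate(curves)
        assert abs(est.mu - mu) < sd
        assert est.window[0] < est.window[1]

    def test_slow_growth_uses_fallback_path(self):
        curves = simulate_growth_curve(
            0.005, config=SimConfig(seed=11, noise_cv=0.03, n_replicates=3)
        )
        est = estimate_growth_rate(curves)
        assert not est.no_growth
        assert est.slow_growth
        assert abs(est.mu - 0.005) < 0.004

    def test_window_excludes_stationary_phase(self):
        # logistic curve saturating at 0.5: the window stays in the early rise
        curves = simulate_growth_curve(
            0.122, config=SimConfig(seed=3, noise_cv=0.03, n_replicates=1)
        )
        est = estimate_growth_rate(curves)
        assert est.window[1] <= 20.0

    def test_too_few_points_rejected(self):
        c = GrowthCurve(times=[0.0, 2.0, 4.0], od600=[0.02, 0.03, 0.04])
        with pytest.raises(GrowthDataError):
            estimate_growth_rate([c])

    def test_blank_subtraction_applied(self):
        base = exponential_curve(mu=0.1)
        shifted = GrowthCurve(times=base.times, od600=base.od600 + 0.05)
        cfg = GrowthRateConfig(blank=0.05)
        est = estimate_growth_rate([shifted], cfg)
        assert est.mu == pytest.approx(0.1, rel=1e-9)

    def test_invalid_curve_rejected(self):
        with pytest.raises(GrowthDataError):
            GrowthCurve(times=[0.0, 1.0, 1.0, 2.0], od600=[1, 2, 3, 4])
        with pytest.raises(GrowthDataError):
            GrowthCurve(times=[0.0, 1.0], od600=[0.1, -0.1])


class TestScfaRatio:
    def make_series(self, y_ac, y_prop):
        return simulate_fermentation(
            sugars={"glcnac": 25.0},
            acid_yields={"glcnac": (y_ac, y_prop)},
            consumption_rates={"glcnac": 1.0},
            config=SimConfig(seed=0, noise_cv=0.0),
        )

    @pytest.mark.parametrize("y_ac,y_prop,expected",
                             [(1.0, 1.0, 1.0), (1.0, 2.0, 0.5), (2.0, 1.0, 2.0)])
    def test_yield_stoichiometry_recovered(self, y_ac, y_prop, expected):
        res = scfa_ratio(self.make_series(y_ac, y_prop))
        assert res.ratio == pytest.approx(expected, rel=1e-9)

    def test_no_propionate_gives_undefined_ratio(self):
        res = scfa_ratio(self.make_series(1.0, 0.0))
        assert not res.defined and res.ratio is None

    def test_missing_analyte_rejected(self):
        ts = MetaboliteTimeSeries(times=[0.0, 1.0],
                                  concentrations={"acetate": [0.0, 1.0]})
        with pytest.raises(GrowthDataError, match="propionate"):
            scfa_ratio(ts)

    @given(st.floats(0.1, 10.0))
    def test_invariant_to_shared_dilution(self, factor):
        ts = self.make_series(1.75, 1.0)
        diluted = MetaboliteTimeSeries(
            times=ts.times,
            concentrations={k: v * factor for k, v in ts.concentrations.items()},
        )
        assert scfa_ratio(diluted).ratio == pytest.approx(
            scfa_ratio(ts).ratio, rel=1e-9
        )


class TestConsumptionRates:
    def two_sugar_series(self, r1, r2, noise=0.0, seed=0):
        # hourly sampling so even a fast-depleting sugar has a well-sampled
        # depletion phase
        grid = tuple(np.arange(0.0, 48.1, 1.0))
        return simulate_fermentation(
            sugars={"glc": 12.5, "glcnac": 12.5},
            acid_yields={"glc": (1.0, 1.0), "glcnac": (1.0, 1.0)},
            consumption_rates={"glc": r1, "glcnac": r2},
            config=SimConfig(seed=seed, noise_cv=noise, grid=grid),
        )

    def test_equal_rates_declared_equal(self):
        ts = self.two_sugar_series(1.0, 1.0, noise=0.01, seed=2)
        out = consumption_rates(ts, ["glc", "glcnac"], compare=("glc", "glcnac"))
        assert out["equal_rates"]
        assert out["rates"]["glc"].rate == pytest.approx(1.0, rel=0.1)

    def test_distinct_rates_declared_unequal(self):
        ts = self.two_sugar_series(1.0, 2.0, noise=0.005, seed=2)
        out = consumption_rates(ts, ["glc", "glcnac"], compare=("glc", "glcnac"))
        assert not out["equal_rates"]

    def test_flat_sugar_has_near_zero_rate(self):
        ts = self.two_sugar_series(1.0, 0.0, noise=0.0)
        out = consumption_rates(ts, ["glcnac"])
        assert out["rates"]["glcnac"].rate == pytest.approx(0.0, abs=1e-12)

    def test_depletion_phase_excludes_exhausted_tail(self):
        # sugar exhausted at 12.5 h; the flat tail must not dilute the slope
        ts = self.two_sugar_series(1.0, 0.0)
        out = consumption_rates(ts, ["glc"])
        assert out["rates"]["glc"].rate == pytest.approx(1.0, rel=1e-6)

    def test_missing_analyte_rejected(self):
        ts = self.two_sugar_series(1.0, 1.0)
        with pytest.raises(GrowthDataError):
            consumption_rates(ts, ["fructose"])


class TestCsvInterchange:
    def test_growth_csv_roundtrip(self, tmp_path):
        curves = simulate_growth_curve(
            0.1, config=SimConfig(seed=1, noise_cv=0.03, n_replicates=2),
            condition="GlcNAc",
        )
        p = str(tmp_path / "g.csv")
        write_growth_csv(curves, p)
        back = read_growth_csv(p)
        assert set(back) == {"GlcNAc"}
        assert len(back["GlcNAc"]) == 2
        np.testing.assert_allclose(back["GlcNAc"][0].od600, curves[0].od600)

    def test_hplc_csv_roundtrip(self, tmp_path):
        ts = simulate_fermentation(
            {"glcnac": 25.0}, {"glcnac": (1.75, 1.0)}, {"glcnac": 1.0},
            config=SimConfig(seed=1, noise_cv=0.01), condition="GlcNAc",
        )
        p = str(tmp_path / "h.csv")
        write_hplc_csv([ts], p)
        back = read_hplc_csv(p)
        np.testing.assert_allclose(
            back["GlcNAc"].concentrations["acetate"],
            ts.concentrations["acetate"],
        )
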