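"""Quenching-titration fits against exact data, generators and OLS oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npbind import synthdata
from npbind.exceptions import (
    DegenerateFitWarning,
    ExcludedPointsWarning,
    FitError,
    NonPhysicalWarning,
)
from npbind.quenchfit import (
    BindingFit,
    QuenchBindingModel,
    QuenchTitration,
    classify_quenching,
    fit_hill_double_log,
    fit_lehrer,
    fit_stern_volmer,
    fit_titrations,
)

from .conftest import make_titration, ols_oracle


class TestQuenchTitration:
    def test_f0_comes_from_the_zero_row(self):
        t = make_titration(f0=1234.0)
        assert t.f0 == 1234.0

    @pytest.mark.parametrize(
        "q, f, msg",
        [
            ([0, 10, 20, 30], [1, 1, 1], "equal length"),
            ([10, 20, 30, 40], [1, 1, 1, 1], "zero-concentration"),
            ([0, 0, 10, 20, 30], [1, 1, 1, 1, 1], "zero-concentration"),
            ([0, 10, 20], [1, 1, 1], "distinct nonzero"),
            ([0, 10, 20, 30], [1, -1, 1, 1], "> 0"),
        ],
    )
    def test_invalid_titrations_are_rejected(self, q, f, msg):
        with pytest.raises(ValueError, match=msg):
            QuenchTitration(298.0, q, f)


class TestSternVolmer:
    def test_exact_line_recovered(self):
        # F0/F = 1 + 0.05 Q over Q in 0..60
        fit = fit_stern_volmer(make_titration(ksv=0.05))
        assert fit.ksv == pytest.approx(0.05, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_generator_round_trip_noise_free(self):
        t = synthdata.gen_quench_titration(
            "static_hill", ka=6.2e-2, n_sites=1.0, noise_sd=0.0, seed=7
        )
        fit = fit_stern_volmer(t)
        assert fit.ksv == pytest.approx(6.2e-2, abs=1e-9)

    def test_noisy_fit_matches_normal_equation_oracle(self):
        t = synthdata.gen_quench_titration(
            "static_hill", ka=6.2e-2, n_sites=1.0, noise_sd=0.01, seed=11
        )
        fit = fit_stern_volmer(t)
        q, f = t.nonzero()
        slope, intercept, r2 = ols_oracle(q, t.f0 / f)
        assert fit.ksv == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        assert fit.r_squared == pytest.approx(r2, rel=1e-9)
        assert fit.ksv == pytest.approx(6.2e-2, rel=0.05)

    def test_enhancement_points_excluded_with_warning(self):
        q = np.array([0.0, 10, 20, 30, 40, 50])
        f = 1000.0 / (1 + 0.05 * q)
        f[-1] = 1100.0  # enhancement artifact
        t = QuenchTitration(298.0, q, f)
        with pytest.warns(ExcludedPointsWarning):
            fit = fit_stern_volmer(t)
        assert fit.points_used == 4
        assert fit.n_excluded == 1
        assert fit.ksv == pytest.approx(0.05, abs=1e-12)

    def test_too_few_points_raise(self):
        q = np.array([0.0, 10, 20, 30])
        f = np.array([1000.0, 1100, 1200, 900])  # two enhancements
        with pytest.warns(ExcludedPointsWarning):
            with pytest.raises(FitError, match=">=3"):
                fit_stern_volmer(QuenchTitration(298.0, q, f))

    def test_no_quenching_is_flagged_degenerate(self):
        t = QuenchTitration(298.0, [0, 10, 20, 30], [500.0] * 4)
        with pytest.warns(DegenerateFitWarning):
            fit = fit_stern_volmer(t)
        assert fit.ksv == 0.0
        assert fit.degenerate


class TestLehrer:
    def test_full_quenchable_data_gives_theta_one(self):
        # theta = 1: the Lehrer plot reduces to the Stern-Volmer model
        fit = fit_lehrer(make_titration(ksv=0.05))
        assert fit.theta == pytest.approx(1.0, abs=1e-10)
        assert fit.ksv == pytest.approx(0.05, rel=1e-10)

    def test_generator_round_trip_partial_accessibility(self):
        t = synthdata.gen_quench_titration(
            "lehrer", ksv=6.2e-2, theta=0.561, noise_sd=0.0, seed=3
        )
        fit = fit_lehrer(t)
        assert fit.theta == pytest.approx(0.561, abs=1e-9)
        assert fit.ksv == pytest.approx(6.2e-2, abs=1e-9)
        assert fit.theta_physical

    def test_matches_reciprocal_transform_oracle(self):
        t = synthdata.gen_quench_titration(
            "lehrer", ksv=0.08, theta=0.7, noise_sd=0.005, seed=5
        )
        fit = fit_lehrer(t)
        q, f = t.nonzero()
        keep = f < t.f0
        slope, intercept, _ = ols_oracle(1.0 / q[keep], t.f0 / (t.f0 - f[keep]))
        assert fit.theta == pytest.approx(1.0 / intercept, rel=1e-12)
        assert fit.ksv == pytest.approx(intercept / slope, rel=1e-12)

    def test_under_determined_input_raises(self):
        q = np.array([0.0, 10, 20, 30])
        f0 = 1000.0
        f = f0 / (1 + 0.05 * q)
        f[2:] = f0  # only one quenched point left
        with pytest.warns(ExcludedPointsWarning):
            with pytest.raises(FitError):
                fit_lehrer(QuenchTitration(298.0, q, f))

    def test_non_physical_theta_warns(self):
        # concave-down fabricated curve drives the intercept negative
        q = np.array([0.0, 5.0, 10.0, 40.0])
        f = np.array([1000.0, 999.0, 990.0, 200.0])
        with pytest.warns(NonPhysicalWarning):
            fit = fit_lehrer(QuenchTitration(298.0, q, f))
        assert not fit.theta_physical


class TestHillDoubleLog:
    def test_half_quenching_point_fixes_ka(self):
        # Ka = 1, n = 1: F(Q=1) = F0/2 exactly
        q = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0])
        f = 1000.0 / (1.0 + q)
        fit = fit_hill_double_log(QuenchTitration(298.0, q, f))
        assert fit.ka == pytest.approx(1.0, rel=1e-12)
        assert fit.n_sites == pytest.approx(1.0, abs=1e-12)
        assert f[3] == pytest.approx(500.0)

    def test_kd_is_reciprocal_of_ka(self):
        t = synthdata.gen_quench_titration("static_hill", ka=4.35e-1, seed=0)
        fit = fit_hill_double_log(t)
        assert fit.kd * fit.ka == pytest.approx(1.0, abs=1e-15)
        assert fit.kd == pytest.approx(1.0 / 4.35e-1, rel=1e-9)

    def test_fractional_site_number_recovered_by_algebraic_inversion(self):
        ka, n = 0.1, 0.8
        t = synthdata.gen_quench_titration(
            "static_hill", ka=ka, n_sites=n, noise_sd=0.0, seed=1
        )
        fit = fit_hill_double_log(t)
        # oracle: invert the generating law at two points
        q1, q2 = 10.0, 40.0
        y = lambda q: np.log10(ka * q**n)
        n_oracle = (y(q2) - y(q1)) / (np.log10(q2) - np.log10(q1))
        ka_oracle = 10 ** (y(q1) - n_oracle * np.log10(q1))
        assert fit.n_sites == pytest.approx(n_oracle, rel=1e-9)
        assert fit.ka == pytest.approx(ka_oracle, rel=1e-9)
        assert fit.n_sites == pytest.approx(n, rel=1e-9)

    def test_no_quenching_names_the_cause(self):
        t = QuenchTitration(298.0, [0, 10, 20, 30], [500.0] * 4)
        with pytest.raises(FitError, match="no quenching|usable"):
            fit_hill_double_log(t)


class TestMechanismClassification:
    def test_decreasing_ksv_is_static(self, ksv_by_temperature):
        assert classify_quenching(ksv_by_temperature) == "static"

    def test_increasing_ksv_is_dynamic(self, ksv_by_temperature):
        temps = [t for t, _ in ksv_by_temperature]
        ksvs = [k for _, k in ksv_by_temperature]
        reversed_series = list(zip(temps, ksvs[::-1]))
        assert classify_quenching(reversed_series) == "dynamic"

    def test_non_monotone_is_indeterminate(self):
        series = [(298.0, 6.2e-2), (303.0, 3.0e-2), (308.0, 4.5e-2)]
        assert classify_quenching(series) == "indeterminate"

    def test_ties_are_indeterminate(self):
        assert classify_quenching([(298.0, 0.05), (303.0, 0.05)]) == "indeterminate"

    def test_single_temperature_errors(self):
        with pytest.raises(ValueError):
            classify_quenching([(298.0, 0.05)])

    @given(
        ksvs=st.lists(
            st.floats(min_value=1e-3, max_value=1.0), min_size=2, max_size=6, unique=True
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_antisymmetric_under_order_reversal(self, ksvs):
        """Reversing a monotone Ksv series swaps static and dynamic;
        series with ties (after rounding) stay indeterminate both ways."""
        temps = [298.0 + 5 * i for i in range(len(ksvs))]
        fwd = classify_quenching(list(zip(temps, sorted(ksvs, reverse=True))))
        rev = classify_quenching(list(zip(temps, sorted(ksvs))))
        assert (fwd, rev) in {("static", "dynamic"),
                              ("indeterminate", "indeterminate")}
        distinct_after_rounding = len({float(f"{k:.10g}") for k in ksvs}) == len(ksvs)
        if distinct_after_rounding:
            assert (fwd, rev) == ("static", "dynamic")


class TestAgreementAcrossFits:
    def test_all_three_fits_agree_for_simple_static_data(self):
        """theta = 1, n = 1 static data: Ksv == Lehrer Ksv == Ka."""
        t = make_titration(ksv=0.044)
        sv = fit_stern_volmer(t)
        le = fit_lehrer(t)
        hi = fit_hill_double_log(t)
        assert sv.ksv == pytest.approx(0.044, rel=1e-9)
        assert le.ksv == pytest.approx(0.044, rel=1e-9)
        assert hi.ka == pytest.approx(0.044, rel=1e-9)
        assert hi.n_sites == pytest.approx(1.0, abs=1e-9)

    @given(
        slope=st.floats(min_value=-2, max_value=2),
        intercept=st.floats(min_value=-5, max_value=5),
        noise=st.lists(
            st.floats(min_value=-0.5, max_value=0.5), min_size=4, max_size=10
        ),
    )
    @settings(deadline=None, max_examples=60)
    def test_ols_equals_normal_equation_oracle(self, slope, intercept, noise):
        x = np.arange(1.0, len(noise) + 1.0)
        y = intercept + slope * x + np.array(noise)
        if np.ptp(y) == 0:
            return
        from scipy.stats import linregress

        res = linregress(x, y)
        o_slope, o_intercept, o_r2 = ols_oracle(x, y)
        assert res.slope == pytest.approx(o_slope, rel=1e-9, abs=1e-12)
        assert res.intercept == pytest.approx(o_intercept, rel=1e-9, abs=1e-12)
        assert res.rvalue**2 == pytest.approx(o_r2, rel=1e-6, abs=1e-9)


class TestModelResultsSurface:
    def test_model_fit_summary_and_table(self):
        t = synthdata.gen_quench_titration("lehrer", ksv=6.2e-2, theta=0.561, seed=2)
        fit = QuenchBindingModel(t).fit()
        assert isinstance(fit, BindingFit)
        text = fit.summary()
        assert "Ksv" in text and "Kd" in text
        d = fit.to_dict()
        assert d["Kd_uM"] * d["Ka_per_uM"] == pytest.approx(1.0, abs=1e-12)

    def test_from_dataframe_selects_temperature(self):
        import pandas as pd

        frames = [
            make_titration(ksv=k, temperature=temp).to_frame()
            for temp, k in [(298.0, 0.062), (313.0, 0.030)]
        ]
        df = pd.concat(frames, ignore_index=True)
        fit = QuenchBindingModel.from_dataframe(df, temperature=313.0).fit()
        assert fit.temperature == 313.0
        assert fit.ksv == pytest.approx(0.030, rel=1e-9)

    def test_diagnostic_plot_renders(self):
        import matplotlib

        matplotlib.use("Agg")
        t = make_titration(ksv=0.05)
        fit = QuenchBindingModel(t).fit()
        ax = fit.plot()
        assert ax.get_xlabel() == "[Q] (uM)"

    def test_fit_titrations_sorted_by_temperature(self):
        ts = [make_titration(ksv=0.03, temperature=313.0),
              make_titration(ksv=0.062, temperature=298.0)]
        fits = fit_titrations(ts)
        assert [f.temperature for f in fits] == [298.0, 313.0]
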