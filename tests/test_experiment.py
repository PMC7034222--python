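"""Bench data reductions: velocity, mass loss, trend fits, swelling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanoflux as nf
from nanoflux.experiment import FlowExperimentTable

SIZE_LOSS_PAIRS = [(69.0, 1.77), (130.0, 1.60), (140.0, 1.96), (144.0, 2.45)]


class TestVelocityFromTransit:
    @pytest.mark.parametrize("t, expected", [(10.0, 0.47), (8.1, 0.58)])
    def test_bench_range(self, channel, t, expected):
        assert nf.mean_velocity_from_transit(channel, t) == pytest.approx(
            expected, abs=0.005)

    def test_long_transit_limit(self, channel):
        assert nf.mean_velocity_from_transit(channel, 1e9) < 1e-8

    def test_invalid_time(self, channel):
        with pytest.raises(nf.InvalidInputError):
            nf.mean_velocity_from_transit(channel, 0.0)


class TestMassLossPercent:
    @pytest.mark.parametrize("inlet, outlet, expected", [
        (1.000, 0.990, 1.0),
        (1.000, 1.000, 0.0),
        (2.008, 1.8883, 5.96),  # inverts the measured 5.96% loss
    ])
    def test_examples(self, inlet, outlet, expected):
        assert nf.mass_loss_percent(inlet, outlet) == pytest.approx(expected, abs=0.005)

    def test_outlet_exceeding_inlet_flagged(self):
        with pytest.raises(nf.DataQualityError):
            nf.mass_loss_percent(1.0, 1.01)

    @given(inlet=st.floats(0.1, 100.0), frac=st.floats(0.0, 1.0),
           scale=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, inlet, frac, scale):
        outlet = inlet * frac
        a = nf.mass_loss_percent(inlet, outlet)
        b = nf.mass_loss_percent(inlet * scale, outlet * scale)
        assert a == pytest.approx(b, abs=1e-9)


class TestFitTrend:
    def test_quadratic_size_loss_correlation(self):
        """The four (size, average loss) pairs correlate quadratically, R ~ 0.96."""
        x, y = zip(*SIZE_LOSS_PAIRS)
        fit = nf.fit_trend(x, y, "quadratic")
        assert fit.correlation_R == pytest.approx(0.9635, abs=0.002)

    @pytest.mark.parametrize("family, coeffs", [
        ("linear", (1.5, -0.3)),
        ("quadratic", (0.4, -2.0, 3.0)),
        ("cubic", (0.02, -0.3, 1.0, -0.6)),
    ])
    def test_noiseless_parameter_recovery(self, family, coeffs):
        x = np.linspace(1.0, 6.0, 9)
        y = np.polyval(coeffs, x)
        fit = nf.fit_trend(x, y, family)
        assert np.allclose(fit.coefficients, coeffs, rtol=1e-8)
        assert fit.correlation_R == pytest.approx(1.0, abs=1e-9)

    def test_power_recovery(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        fit = nf.fit_trend(x, 3.0 * x**-0.5, "power")
        assert fit.coefficients[0] == pytest.approx(3.0, rel=1e-9)
        assert fit.coefficients[1] == pytest.approx(-0.5, rel=1e-9)

    def test_constant_response_degenerate_not_raising(self):
        fit = nf.fit_trend([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], "linear")
        assert fit.degenerate
        assert np.isnan(fit.correlation_R)

    def test_singular_design_raises(self):
        with pytest.raises(nf.InvalidInputError):
            nf.fit_trend([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0], "quadratic")

    def test_too_few_points(self):
        with pytest.raises(nf.InvalidInputError):
            nf.fit_trend([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "cubic")

    def test_power_requires_positive_data(self):
        with pytest.raises(nf.InvalidInputError):
            nf.fit_trend([-1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "power")

    @pytest.mark.parametrize("a, b", [(2.0, 5.0), (0.1, -3.0)])
    def test_correlation_invariant_to_affine_x(self, a, b):
        x = np.linspace(60.0, 150.0, 8)
        rng = np.random.default_rng(0)
        y = 0.001 * x**2 - 0.1 * x + rng.normal(0.0, 0.5, x.size)
        r1 = nf.fit_trend(x, y, "quadratic").correlation_R
        r2 = nf.fit_trend(a * x + b, y, "quadratic").correlation_R
        assert r1 == pytest.approx(r2, abs=1e-9)


def _make_table(channel, loss_by_size, n_rep=3, velocity=0.5, amounts=(2.0, 3.0, 4.0)):
    rows = []
    for size, loss in loss_by_size.items():
        for amount in amounts:
            for rep in range(1, n_rep + 1):
                rows.append({
                    "formulation": f"f{size:g}", "size_nm": size,
                    "inlet_amount_g": amount, "replicate": rep,
                    "transit_time_s": channel.length * 100.0 / velocity,
                    "inlet_mass_g": amount,
                    "outlet_mass_g": amount * (1.0 - loss / 100.0),
                })
    return FlowExperimentTable(pd.DataFrame(rows))


class TestSizeCorrelationReport:
    def test_planted_linear_trend_flags_linear(self, channel):
        loss_by_size = {70.0: 1.0, 100.0: 1.6, 130.0: 2.2, 150.0: 2.6}
        table = _make_table(channel, loss_by_size)
        report = nf.size_correlation_report(table, channel)
        groups = {}
        for fit in report:
            groups.setdefault(fit.group, []).append(fit)
        for label, fits in groups.items():
            assert fits[0].family == "linear"  # preferred family listed first
            assert fits[0].correlation_R > 0.98

    def test_permuted_sizes_destroy_trend(self, channel):
        losses = [1.0, 1.6, 2.2, 2.6]
        permuted = dict(zip([70.0, 100.0, 130.0, 150.0],
                            [losses[i] for i in (2, 0, 3, 1)]))
        table = nf.size_correlation_report(_make_table(channel, permuted), channel)
        linear = [f for f in table if f.family == "linear"]
        assert all(abs(f.correlation_R) < 0.5 for f in linear)

    def test_single_replicate_equals_replicate_mean_path(self, channel):
        loss_by_size = {70.0: 1.2, 100.0: 1.8, 130.0: 2.0, 150.0: 2.9}
        r3 = nf.size_correlation_report(_make_table(channel, loss_by_size, n_rep=3),
                                        channel)
        r1 = nf.size_correlation_report(_make_table(channel, loss_by_size, n_rep=1),
                                        channel)
        for a, b in zip(r3, r1):
            assert a.family == b.family and a.group == b.group
            assert a.correlation_R == pytest.approx(b.correlation_R, abs=1e-12)

    def test_insufficient_sizes_warn_not_drop(self, channel):
        table = _make_table(channel, {70.0: 1.0, 100.0: 2.0})
        with pytest.warns(UserWarning, match="distinct sizes"):
            report = nf.size_correlation_report(table, channel)
        assert report == []

    def test_overall_grouping(self, channel):
        loss_by_size = {70.0: 1.0, 100.0: 1.6, 130.0: 2.2, 150.0: 2.6}
        report = nf.size_correlation_report(_make_table(channel, loss_by_size),
                                            channel, grouping="overall")
        assert {f.group for f in report} == {"overall"}


class TestFlowExperimentTable:
    def test_schema_and_quality_checks(self, channel):
        good = _make_table(channel, {70.0: 1.0, 100.0: 2.0, 130.0: 1.5})
        df = good.data.copy()
        df.loc[0, "outlet_mass_g"] = df.loc[0, "inlet_mass_g"] + 1.0
        with pytest.raises(nf.DataQualityError):
            FlowExperimentTable(df)
        with pytest.raises(nf.InvalidInputError):
            FlowExperimentTable(df.drop(columns=["transit_time_s"]))

    def test_csv_round_trip(self, channel, tmp_path):
        table = _make_table(channel, {70.0: 1.0, 100.0: 2.0, 130.0: 1.5})
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = FlowExperimentTable.from_csv(path)
        pd.testing.assert_frame_equal(
            back.data, table.data, check_exact=False, rtol=1e-12)

    def test_replicate_mean_equivalence_noiseless(self, channel):
        """Three identical replicates analyse exactly like their mean."""
        table = _make_table(channel, {70.0: 1.2, 100.0: 1.8, 130.0: 2.4})
        means = table.condition_means(channel)
        raw = table.with_derived(channel)
        for _, row in means.iterrows():
            sub = raw[(raw.formulation == row.formulation)
                      & (raw.inlet_amount_g == row.inlet_amount_g)]
            assert row.loss_percent == pytest.approx(sub.loss_percent.mean())


class TestSwelling:
    @pytest.mark.parametrize("swollen, expected", [
        (12.8, 60.0),   # the pH-11 maximum on an 8 mg dry gel
        (8.0, 0.0),
        (11.2, 40.0),   # lower bound of the reported 40-50% peak band
    ])
    def test_ratio_examples(self, swollen, expected):
        rec = nf.SwellingRecord(dry_weight=8.0, swollen_weight=swollen, pH=11.0)
        assert nf.swelling_ratio(rec) == pytest.approx(expected)

    def test_invalid_records(self):
        with pytest.raises(nf.InvalidInputError):
            nf.SwellingRecord(dry_weight=0.0, swollen_weight=1.0)
        with pytest.raises(nf.InvalidInputError):
            nf.SwellingRecord(dry_weight=8.0, swollen_weight=9.0, pH=0.5)

    def test_peak_detection(self):
        t = np.arange(0.0, 8.0, 0.5)
        ratios = 60.0 * np.exp(-((t - 1.5) ** 2))
        when, how_much = nf.swelling_peak(t, ratios)
        assert when == 1.5 and how_much == 60.0

    def test_peak_of_empty_series(self):
        with pytest.raises(nf.InvalidInputError):
            nf.swelling_peak([], [])
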