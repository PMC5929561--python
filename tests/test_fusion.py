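"""Fusion-kinetics pipeline: I/O round trips, normalisation, regression
rates, endpoints, and recovery of generator parameters."""

import numpy as np
import pytest

from cardiofuse import fusion as fu


def line_series(pair_id="p0", group="CM-CM", slope=2.0, icept=90.0,
                metric="angle_deg", t=None):
    t = np.arange(1.0, 20.0) if t is None else t
    return fu.PairTimeseries(pair_id, group, t, icept + slope * t, metric)


class TestPairTimeseries:
    def test_angle_bounds_enforced(self):
        with pytest.raises(ValueError):
            fu.PairTimeseries("p", "CM-CM", [1, 2], [90.0, 190.0], "angle_deg")

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError):
            fu.PairTimeseries("p", "CM-CM", [2, 1], [90.0, 91.0], "angle_deg")

    def test_gaps_dropped(self):
        s = fu.PairTimeseries("p", "CM-CM", [1, 2, 3],
                              [90.0, np.nan, 92.0], "angle_deg")
        assert s.times.tolist() == [1.0, 3.0]


class TestNormalize:
    def test_reference_is_100_percent(self):
        s = line_series(metric="length_um", slope=-3.0, icept=500.0)
        n = fu.normalize_length(s)
        assert n.value_at(1.0) == pytest.approx(100.0)

    def test_constant_series_stays_100(self):
        s = line_series(metric="length_um", slope=0.0, icept=400.0)
        assert np.allclose(fu.normalize_length(s).values, 100.0)

    def test_halving_series_ends_at_50(self):
        t = np.arange(1.0, 20.0)
        vals = 400.0 * (1.0 - 0.5 * (t - 1.0) / 18.0)
        s = fu.PairTimeseries("p", "CM-CM", t, vals, "length_um")
        assert fu.normalize_length(s).value_at(19.0) == pytest.approx(50.0)

    def test_missing_reference_errors(self):
        s = fu.PairTimeseries("p", "CM-CM", [5.0, 6.0], [400.0, 398.0],
                              "length_um")
        with pytest.raises(ValueError):
            fu.normalize_length(s)

    def test_normalized_slope_closed_form(self):
        """normalise-then-fit returns 100 * slope / value(1 h) per hour."""
        s = line_series(metric="length_um", slope=-3.0, icept=500.0)
        rs = fu.fit_rate([fu.normalize_length(s)], "norm_length_pct",
                         group="CM-CM")
        assert rs.mean == pytest.approx(100.0 * -3.0 / 497.0)


class TestFitRate:
    def test_exact_line(self):
        rs = fu.fit_rate([line_series(slope=2.0)], "angle_deg", group="CM-CM")
        assert rs.mean == pytest.approx(2.0)
        assert rs.sd == 0.0
        assert rs.pooled_slope == pytest.approx(2.0)

    def test_pooled_equals_per_pair_for_identical_pairs(self):
        pairs = [line_series(pair_id=f"p{i}", slope=1.5) for i in range(4)]
        rs = fu.fit_rate(pairs, "angle_deg", group="CM-CM")
        assert rs.n == 4
        assert rs.pooled_slope == pytest.approx(rs.mean)

    def test_too_few_points_rejected(self):
        s = fu.PairTimeseries("p", "CM-CM", [1.0, 2.0], [90.0, 92.0],
                              "angle_deg")
        with pytest.raises(ValueError):
            fu.fit_rate([s], "angle_deg", group="CM-CM")


class TestEndpointStats:
    def test_single_pair(self):
        stats = fu.endpoint_stats([line_series(slope=1.0, icept=90.0)],
                                  "angle_deg", 19.0, group="CM-CM")
        assert stats == (pytest.approx(109.0), 0.0, 1)

    def test_no_data_at_time_errors(self):
        with pytest.raises(ValueError):
            fu.endpoint_stats([line_series()], "angle_deg", 40.0,
                              group="CM-CM")


class TestSyntheticGenerator:
    def test_deterministic_given_seed(self):
        a = fu.synth_pair_timeseries(fu.DEFAULT_ANGLE_SPECS, "angle_deg",
                                     seed=11)
        b = fu.synth_pair_timeseries(fu.DEFAULT_ANGLE_SPECS, "angle_deg",
                                     seed=11)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))

    def test_noise_free_exact_recovery(self):
        specs = [fu.GroupSpec("CM-CM", 0.95, 90.0, 0.0, 5)]
        series = fu.synth_pair_timeseries(specs, "angle_deg", seed=0)
        rs = fu.fit_rate(series, "angle_deg", group="CM-CM")
        assert rs.mean == pytest.approx(0.95, abs=1e-9)
        assert rs.sd == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_sampling_error(self):
        """slope 1, noise SD 5, n = 50: mean slope within 3 SE of truth."""
        specs = [fu.GroupSpec("CM-CM", 1.0, 90.0, 5.0, 50)]
        series = fu.synth_pair_timeseries(specs, "angle_deg", seed=5)
        rs = fu.fit_rate(series, "angle_deg", group="CM-CM")
        se = rs.sd / np.sqrt(rs.n)
        assert abs(rs.mean - 1.0) < 3.0 * max(se, 1e-3)

    def test_group_rate_ordering(self):
        """|rate|: CM-CF > CF-CF > CM-CM for both angle and length."""
        for specs, metric in ((fu.DEFAULT_ANGLE_SPECS, "angle_deg"),
                              (fu.DEFAULT_LENGTH_SPECS, "length_um")):
            series = fu.synth_pair_timeseries(specs, metric, seed=2)
            rates = {rs.group: abs(rs.mean)
                     for rs in fu.fit_rate(series, metric)}
            assert rates["CM-CF"] > rates["CF-CF"] > rates["CM-CM"]


class TestRoundTrip:
    def test_spreadsheet_round_trip(self, tmp_path):
        angle = fu.synth_pair_timeseries(fu.DEFAULT_ANGLE_SPECS[:2],
                                         "angle_deg", seed=3)
        length = fu.synth_pair_timeseries(fu.DEFAULT_LENGTH_SPECS[:2],
                                          "length_um", seed=4)
        path = tmp_path / "pairs.xlsx"
        fu.write_pair_table(angle + length, path)
        back = fu.read_pair_table(path)
        got = {(s.group, s.pair_id, s.metric): s for s in back}
        assert len(back) == len(angle) + len(length)
        for s in angle + length:
            b = got[(s.group, s.pair_id, s.metric)]
            np.testing.assert_allclose(b.values, s.values, rtol=1e-12)

    def test_csv_long_format(self, tmp_path):
        path = tmp_path / "pairs.csv"
        with open(path, "w") as f:
            f.write("pair_id,group,time_hr,angle_deg\n")
            for t in range(1, 6):
                f.write(f"p1,CM-CM,{t},{90 + 2 * t}\n")
        series = fu.read_pair_table(path)
        assert len(series) == 1
        assert fu.fit_rate(series, "angle_deg",
                           group="CM-CM").mean == pytest.approx(2.0)

    def test_group_sizes_preserved(self, tmp_path):
        angle = fu.synth_pair_timeseries(fu.DEFAULT_ANGLE_SPECS, "angle_deg",
                                         seed=9)
        path = tmp_path / "pairs.xlsx"
        fu.write_pair_table(angle, path)
        back = fu.read_pair_table(path)
        sizes = {}
        for s in back:
            sizes[s.group] = sizes.get(s.group, 0) + 1
        expect = {sp.group: sp.n_pairs for sp in fu.DEFAULT_ANGLE_SPECS}
        assert sizes == expect

    def test_empty_sheet_warns(self, tmp_path):
        import pandas as pd
        path = tmp_path / "empty.xlsx"
        df = pd.DataFrame({("G", "p"): []}, index=pd.Index([], name="t"))
        with pd.ExcelWriter(path) as xl:
            df.to_excel(xl, sheet_name="angle")
        with pytest.warns(UserWarning):
            out = fu.read_pair_table(path)
        assert out == []
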