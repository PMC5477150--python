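"""Two-point fitting, prediction, window matching and multi-point validation."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lctrs
from lctrs.calibration import fit_least_squares, sequential_match
from lctrs.core import CalibrationLine, MatchConfig, PeakList


def brute_force_ols(x, y, iterations=80):
    """Grid-refinement minimiser of the summed squared vertical residuals.

    Independent of the closed-form fit: searches (slope, intercept) space on a
    shrinking 21x21 grid around the running optimum.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def sse(a, b):
        r = y - (a * x + b)
        return float(r @ r)

    a0, b0 = 0.0, float(y.mean())
    wa, wb = 20.0, 4.0 * max(1.0, float(np.abs(y).max()))
    for _ in range(iterations):
        aa = np.linspace(a0 - wa, a0 + wa, 21)
        bb = np.linspace(b0 - wb, b0 + wb, 21)
        best = min(((sse(a, b), a, b) for a in aa for b in bb))
        _, a0, b0 = best
        wa *= 0.35
        wb *= 0.35
    return a0, b0


class TestTwoPointFit:
    def test_worked_example_coefficients(self):
        """Line through (19.803, 21.014) and (33.035, 35.170)."""
        line = lctrs.fit_two_point((19.803, 33.035), (21.014, 35.170))
        assert round(line.slope, 4) == 1.0698
        assert round(line.intercept, 4) == -0.1719
        assert line.method == "two_point"
        assert line.r is None

    def test_identity_map(self):
        line = lctrs.fit_two_point((7.0, 19.0), (7.0, 19.0))
        assert line.slope == pytest.approx(1.0)
        assert line.intercept == pytest.approx(0.0, abs=1e-12)

    @given(
        s1=st.floats(1, 50),
        ds=st.floats(0.5, 30),
        t1=st.floats(1, 50),
        t2=st.floats(1, 60),
    )
    @settings(derandomize=True)
    def test_interpolates_both_points(self, s1, ds, t1, t2):
        s2 = s1 + ds
        line = lctrs.fit_two_point((s1, s2), (t1, t2))
        assert line(s1) == pytest.approx(t1, abs=1e-9)
        assert line(s2) == pytest.approx(t2, abs=1e-9)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            lctrs.fit_two_point((5.0, 5.0), (6.0, 7.0))


class TestPredict:
    @pytest.mark.parametrize(
        "st_r, expected", [(22.110, 23.481), (30.319, 32.263)]
    )
    def test_worked_example_predictions(self, st_r, expected):
        """The reported line maps the analyte consensus times as printed."""
        line = CalibrationLine(1.0698, -0.1719, method="two_point")
        preds = lctrs.predict(line, {"analyte": st_r})
        assert round(preds["analyte"], 3) == expected

    def test_identity_line(self):
        line = CalibrationLine(1.0, 0.0)
        assert lctrs.predict(line, {"a": 17.3})["a"] == 17.3


class TestMatchPeaks:
    def test_worked_example_assignment(self):
        """Both analytes find their sample peak inside a 0.6 min window."""
        line = CalibrationLine(1.0698, -0.1719, method="two_point")
        preds = lctrs.predict(
            line, {"Chonglou saponin VI": 22.110, "Chonglou saponin II": 30.319}, "two_point"
        )
        peaks = PeakList(times=(21.014, 22.898, 32.679, 35.170))
        cfg = MatchConfig(t_r_window=0.6, t_r_limit=0.5)
        res = lctrs.match_peaks(preds, peaks, cfg)
        vi = res.match_for("Chonglou saponin VI")
        ii = res.match_for("Chonglou saponin II")
        assert (vi.peak, ii.peak) == (22.898, 32.679)
        assert round(vi.delta, 3) == 0.583
        assert round(ii.delta, 3) == 0.416
        assert res.success

    def test_empty_window_leaves_unassigned(self):
        preds = lctrs.predict(CalibrationLine(1.0, 0.0), {"a": 10.0}, "two_point")
        res = lctrs.match_peaks(preds, PeakList(times=(20.0,)), MatchConfig())
        assert res.match_for("a").peak is None
        assert not res.success

    def test_exact_peak_gives_zero_delta(self):
        preds = lctrs.predict(CalibrationLine(1.0, 0.0), {"a": 10.0}, "two_point")
        res = lctrs.match_peaks(preds, PeakList(times=(10.0,)), MatchConfig())
        assert res.match_for("a").delta == 0.0

    def test_tie_prefers_earlier_peak(self):
        preds = lctrs.predict(CalibrationLine(1.0, 0.0), {"a": 10.0}, "two_point")
        res = lctrs.match_peaks(preds, PeakList(times=(9.5, 10.5)), MatchConfig())
        assert res.match_for("a").peak == 9.5

    def test_non_series_conflict_resolved_by_smaller_delta(self):
        # predictions far apart (no series) whose windows share one peak
        preds = lctrs.predict(
            CalibrationLine(1.0, 0.0), {"a": 9.0, "b": 12.0}, "two_point"
        )
        cfg = MatchConfig(t_r_window=2.0, t_r_limit=0.5, series_gap=1.0)
        res = lctrs.match_peaks(preds, PeakList(times=(10.9,)), cfg)
        assert res.match_for("b").peak == 10.9
        assert res.match_for("a").peak is None

    def test_enlarging_window_never_drops_assignments(self):
        """Monotone degradation: a wider window can only add assignments."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            preds = lctrs.predict(
                CalibrationLine(1.0, 0.0),
                {f"a{i}": float(t) for i, t in enumerate(sorted(rng.uniform(5, 30, 4)))},
                "two_point",
            )
            peaks = PeakList(times=tuple(sorted(rng.uniform(5, 30, 5))))
            n_prev = -1
            for w in (0.3, 0.6, 1.2, 2.4, 4.8):
                res = lctrs.match_peaks(preds, peaks, MatchConfig(t_r_window=w, t_r_limit=0.2))
                n = sum(m.peak is not None for m in res.matches)
                assert n >= n_prev
                n_prev = n


class TestSequentialMatch:
    def test_close_pair_matched_in_elution_order(self):
        """Least-deviation would send both to the later peak; the series rule
        assigns earlier prediction to earlier peak."""
        preds = lctrs.predict(
            CalibrationLine(1.0, 0.0), {"p5": 9.8, "p6": 10.4}, "two_point"
        )
        # both peaks nearest to p6's prediction
        peaks = PeakList(times=(9.0, 10.5))
        cfg = MatchConfig(t_r_window=1.2, t_r_limit=1.2, series_gap=2.0)
        res = lctrs.match_peaks(preds, peaks, cfg)
        assert res.match_for("p5").peak == 9.0
        assert res.match_for("p6").peak == 10.5
        assert res.match_for("p5").in_series and res.match_for("p6").in_series

    def test_series_of_one_equals_least_delta(self):
        assert sequential_match([10.0], [9.4, 10.1, 12.0]) == [1]

    def test_three_way_series_is_order_preserving_bijection(self):
        """With three predictions and three candidates the returned assignment
        is the unique order-preserving bijection (checked against all 6)."""
        preds = [10.0, 10.6, 11.4]
        peaks = [9.9, 10.8, 11.2]
        got = sequential_match(preds, peaks)
        assert got == [0, 1, 2]
        costs = {
            perm: sum(abs(p - peaks[j]) for p, j in zip(preds, perm))
            for perm in itertools.permutations(range(3))
        }
        ordered = tuple(got)
        monotone = [perm for perm in costs if list(perm) == sorted(perm)]
        assert monotone == [ordered]

    def test_fewer_peaks_than_predictions_leaves_trailing_unassigned(self):
        assert sequential_match([10.0, 10.5, 11.0], [10.2]) == [0, None, None]

    def test_order_preservation_random_series(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            m = rng.integers(2, 5)
            n = rng.integers(1, 6)
            preds = sorted(rng.uniform(5, 15, m))
            peaks = sorted(rng.uniform(5, 15, n))
            out = sequential_match(preds, peaks)
            taken = [j for j in out if j is not None]
            assert taken == sorted(taken)
            assert len(set(taken)) == len(taken)


class TestMultipointValidation:
    def _matched_col4(self, strt):
        line = lctrs.fit_two_point((strt["Chonglou saponin VII"], strt["Chonglou saponin I"]), (21.014, 35.170))
        preds = lctrs.predict(
            line,
            {"Chonglou saponin VI": strt["Chonglou saponin VI"], "Chonglou saponin II": strt["Chonglou saponin II"]},
            "two_point",
        )
        cfg = MatchConfig(t_r_window=0.6, t_r_limit=0.5)
        peaks = PeakList(times=(21.014, 22.898, 32.679, 35.170))
        return lctrs.match_peaks(preds, peaks, cfg), cfg

    def test_worked_example_refit(self):
        """Four-point refit tightens both deviations below the 0.5 min limit."""
        import pandas as pd

        from lctrs.core import StandardRetention

        strt = StandardRetention(
            values=pd.Series(
                {
                    "Chonglou saponin VII": 19.803,
                    "Chonglou saponin VI": 22.110,
                    "Chonglou saponin II": 30.319,
                    "Chonglou saponin I": 33.035,
                }
            ),
            columns_used=frozenset({"consensus"}),
            n=30,
        )
        matched, cfg = self._matched_col4(strt)
        res = lctrs.validate_multipoint(
            matched, (19.803, 33.035), (21.014, 35.170), strt, cfg
        )
        assert round(res.line.slope, 4) == 1.1038
        assert round(res.line.intercept, 4) == -1.1075
        vi = res.match_for("Chonglou saponin VI")
        ii = res.match_for("Chonglou saponin II")
        assert round(vi.predicted, 3) == 23.297
        assert round(ii.predicted, 3) == 32.358
        assert round(vi.delta, 3) == 0.399
        assert round(ii.delta, 3) == 0.321
        assert res.success
        assert res.previous is matched

    def test_two_reference_points_degenerate_to_interpolation(self):
        """With no analytes the refit equals the two-point line to 1e-9."""
        two = lctrs.fit_two_point((10.0, 20.0), (11.0, 22.5))
        ls = fit_least_squares([10.0, 20.0], [11.0, 22.5])
        assert ls.slope == pytest.approx(two.slope, abs=1e-9)
        assert ls.intercept == pytest.approx(two.intercept, abs=1e-9)
        assert ls.r == 1.0

    def test_collinear_points_have_zero_residuals(self, strt):
        names = strt.compounds
        xs = [strt[c] for c in names]
        line = CalibrationLine(1.1, 2.0)
        peaks = PeakList(times=tuple(sorted(line(x) for x in xs)))
        pair_x = (xs[0], xs[-1])
        preds = lctrs.predict(
            lctrs.fit_two_point(pair_x, (line(xs[0]), line(xs[-1]))),
            {c: strt[c] for c in names[1:-1]},
            "two_point",
        )
        matched = lctrs.match_peaks(preds, peaks, MatchConfig())
        res = lctrs.validate_multipoint(matched, pair_x, (line(xs[0]), line(xs[-1])), strt, MatchConfig())
        assert all(m.delta == pytest.approx(0.0, abs=1e-9) for m in res.matches)
        assert res.success

    def test_least_squares_matches_grid_refinement_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = rng.integers(3, 6)
            x = np.sort(rng.uniform(5, 40, n))
            y = 1.1 * x - 0.8 + rng.normal(0, 0.5, n)
            line = fit_least_squares(x, y)
            a, b = brute_force_ols(x, y)
            assert line.slope == pytest.approx(a, abs=1e-4)
            assert line.intercept == pytest.approx(b, abs=1e-4)


class TestRunLctrs:
    def test_full_walkthrough_on_target_column(self, paridis, strt, pair):
        """End-to-end pipeline on the worked target column succeeds."""
        peaks = PeakList(times=tuple(sorted(paridis.times["col4"])))
        cfg = MatchConfig(t_r_window=0.6, t_r_limit=0.5)
        res = lctrs.run_lctrs(strt, pair, (21.014, 35.170), peaks, cfg)
        assert res.success
        assert res.stage == "multi_point"
        assert res.previous.stage == "two_point"
        assert res.assigned == {
            "Chonglou saponin VI": 22.898,
            "Chonglou saponin II": 32.679,
        }
        assert res.match_for("Chonglou saponin VI").delta < 0.5
        # consensus computed from the full matrix, so coefficients sit within
        # a hair of the printed-consensus fit
        assert res.line.slope == pytest.approx(1.1038, abs=2e-3)

    def test_reference_only_peaks_fail(self, strt, pair):
        peaks = PeakList(times=(21.014, 35.170))
        cfg = MatchConfig(t_r_window=0.6, t_r_limit=0.5)
        res = lctrs.run_lctrs(strt, pair, (21.014, 35.170), peaks, cfg)
        assert not res.success
        assert all(m.peak is None for m in res.matches)

    def test_exact_affine_column_is_perfect(self, strt, pair):
        line = CalibrationLine(1.07, -0.4)
        times = {c: line(strt[c]) for c in strt.compounds}
        peaks = PeakList(times=tuple(sorted(times.values())))
        res = lctrs.run_lctrs(
            strt, pair, (times[pair.first], times[pair.second]), peaks, MatchConfig()
        )
        assert res.success
        assert all(m.delta == pytest.approx(0.0, abs=1e-9) for m in res.matches)

    def test_accepts_table_input(self, paridis, pair):
        peaks = PeakList(times=tuple(sorted(paridis.times["col4"])))
        res = lctrs.run_lctrs(paridis, pair, (21.014, 35.170), peaks)
        assert res.success
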