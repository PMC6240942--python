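import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cypsrs import quantification as quant
from cypsrs.synthetic import reference_tables


def peaks_frame(rows):
    return pd.DataFrame(
        rows, columns=["strain", "variant", "replicate", "timepoint_h", "compound", "area"]
    )


class TestRelativeYield:
    def test_single_replicate_ratio(self):
        df = peaks_frame(
            [
                ("s", "s", 1, 72, "IS", 500.0),
                ("s", "s", 1, 72, "2", 1000.0),
            ]
        )
        out = quant.relative_yield(df)
        assert out["mean"].iloc[0] == pytest.approx(2.0)

    def test_replicate_mean_and_sd(self):
        rows = []
        for rep, ratio in enumerate((1.0, 2.0, 3.0), start=1):
            rows.append(("s", "s", rep, 72, "IS", 100.0))
            rows.append(("s", "s", rep, 72, "2", 100.0 * ratio))
        out = quant.relative_yield(peaks_frame(rows))
        assert out["mean"].iloc[0] == pytest.approx(2.0)
        assert out["sd"].iloc[0] == pytest.approx(1.0)
        assert out["n"].iloc[0] == 3

    def test_missing_is_names_group(self):
        df = peaks_frame([("s", "s", 1, 72, "2", 1000.0)])
        with pytest.raises(ValueError, match="internal-standard"):
            quant.relative_yield(df)

    def test_zero_is_area_rejected(self):
        df = peaks_frame(
            [("s", "s", 1, 72, "IS", 0.0), ("s", "s", 1, 72, "2", 10.0)]
        )
        with pytest.raises(ValueError, match="non-positive"):
            quant.relative_yield(df)

    def test_scale_invariance_per_group(self):
        rows = [
            ("s", "s", 1, 72, "IS", 100.0),
            ("s", "s", 1, 72, "2", 250.0),
            ("s", "s", 2, 72, "IS", 400.0),
            ("s", "s", 2, 72, "2", 1000.0),
        ]
        base = quant.relative_yield(peaks_frame(rows))
        scaled_rows = [(s, v, r, t, c, a * 7.5) for s, v, r, t, c, a in rows]
        scaled = quant.relative_yield(peaks_frame(scaled_rows))
        assert np.allclose(base["mean"], scaled["mean"])
        assert base["mean"].iloc[0] == pytest.approx(2.5)


class TestFoldChange:
    def _yields(self):
        return pd.DataFrame(
            {
                "strain": ["WT", "A99I", "X"],
                "compound": ["2", "2", "2"],
                "mean": [23.4, 86.4, 0.0],
            }
        )

    def test_self_is_exactly_one(self):
        assert quant.fold_change(self._yields(), "WT", "WT", "2") == 1.0

    def test_published_product_increase(self):
        fc = quant.fold_change(self._yields(), "A99I", "WT", "2")
        assert round(fc, 1) == 3.7

    def test_published_substrate_depletion(self):
        y = pd.DataFrame(
            {"strain": ["WT", "A99I"], "compound": ["1", "1"], "mean": [15.9, 0.9]}
        )
        assert round(quant.fold_change(y, "WT", "A99I", "1")) == 18

    def test_zero_reference_is_infinite_not_crash(self):
        assert math.isinf(quant.fold_change(self._yields(), "WT", "X", "2"))

    def test_chained_references_multiply(self):
        y = self._yields()
        fc_ab = quant.fold_change(y, "A99I", "WT", "2")
        fc_wx = 2.0
        y2 = y.copy()
        y2.loc[y2["strain"] == "X", "mean"] = 23.4 / fc_wx
        assert quant.fold_change(y2, "A99I", "X", "2") == pytest.approx(
            fc_ab * quant.fold_change(y2, "WT", "X", "2")
        )


class TestStandardCurve:
    def _calibration(self, concs, responses, compound="2", is_area=100.0):
        return pd.DataFrame(
            {
                "compound": compound,
                "concentration_mg_per_L": concs,
                "area": [r * is_area for r in responses],
                "is_area": is_area,
            }
        )

    def test_exact_line(self):
        curve = quant.fit_standard_curve(self._calibration([0, 1, 2], [0, 1, 2]), "2")
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(0.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_on_noisy_points(self):
        rng = np.random.default_rng(5)
        conc = np.array([1.0, 2.0, 5.0, 10.0, 25.0, 50.0])
        resp = 0.09 * conc + rng.normal(0, 0.05, conc.size)
        curve = quant.fit_standard_curve(self._calibration(conc, resp), "2")
        design = np.column_stack([conc, np.ones_like(conc)])
        slope, intercept = np.linalg.solve(design.T @ design, design.T @ resp)
        assert curve.slope == pytest.approx(slope)
        assert curve.intercept == pytest.approx(intercept)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            quant.fit_standard_curve(self._calibration([5, 5], [1, 1.1]), "2")


class TestAbsoluteTiter:
    CURVE = quant.StandardCurve("2", slope=0.09, intercept=0.01, r_squared=1.0,
                                concentration_range=(1.0, 100.0))

    def test_response_at_intercept_is_zero(self):
        out = quant.absolute_titer({"2": 0.01}, {"2": self.CURVE})
        assert out["2"] == 0.0

    def test_shared_response_factor_compound(self):
        """An unidentified derivative on its parent's curve gets the parent's titer."""
        response = 0.09 * 12.5 + 0.01
        out = quant.absolute_titer(
            {"2": response, "7": response}, {"2": self.CURVE}, {"7": "2"}
        )
        assert out["7"] == out["2"] == pytest.approx(12.5)

    def test_mapped_compound_without_curve_raises(self):
        with pytest.raises(KeyError, match="'7'"):
            quant.absolute_titer({"7": 1.0}, {}, {"7": "2"})

    def test_unmapped_compound_excluded(self):
        out = quant.absolute_titer({"2": 1.0, "9": 1.0}, {"2": self.CURVE})
        assert "9" not in out and "2" in out


class TestStrainMetrics:
    @pytest.mark.parametrize(
        "titers, total, oxygenated, content2",
        [
            ({"1": 15.9, "2": 23.4, "3": 0.2, "7": 4.3}, 43.8, 64, 53),
            ({"1": 0.9, "2": 86.4, "3": 0.4, "7": 0.0}, 87.7, 99, 99),
            ({"1": 43.8}, 43.8, 0, 0),
        ],
    )
    def test_specificity_arithmetic(self, titers, total, oxygenated, content2):
        m = quant.strain_metrics(titers, "s")
        assert m.total == pytest.approx(total)
        assert round(m.oxygenated_pct) == oxygenated
        assert round(m.content2_pct) == content2

    def test_total_is_sum_and_fold_change_of_reference_is_one(self):
        titers = {"1": 1.0, "2": 2.0, "3": 3.0, "7": 4.0}
        m = quant.strain_metrics(titers, "s", reference_titers=titers)
        assert m.total == pytest.approx(10.0)
        assert all(fc == 1.0 for fc in m.fold_changes.values())

    def test_zero_total_reports_zero_percent(self):
        m = quant.strain_metrics({}, "empty")
        assert m.total == 0.0 and m.oxygenated_pct == 0.0 and m.content2_pct == 0.0

    def test_reported_screen_rows_are_internally_consistent(self):
        """Every published shake-flask row satisfies total = sum of compounds
        and the printed specificity percentages within 1 point."""
        table = reference_tables().shake_flask_titers
        for row in table.itertuples():
            titers = {"1": row.titer_1, "2": row.titer_2, "3": row.titer_3, "7": row.titer_7}
            m = quant.strain_metrics(titers, row.strain)
            assert m.total == pytest.approx(row.total_mg_per_L, abs=0.15)
            assert abs(round(m.oxygenated_pct) - row.oxygenated_pct) <= 1
            assert abs(round(m.content2_pct) - row.content2_pct) <= 1
            assert 0 <= m.content2_pct <= m.oxygenated_pct + 1


class TestCompareGroups:
    def test_identical_constant_groups_give_one(self):
        assert quant.compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_separated_groups_give_tiny_p(self):
        a = [0.0, 0.001, -0.001]
        b = [1.0, 1.001, 0.999]
        assert quant.compare_groups(a, b) < 1e-3

    def test_welch_matches_permutation_oracle(self):
        """Welch p agrees with a 10^5-resample permutation test on the Welch
        statistic, within Monte-Carlo error."""
        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(0.8, 1.0, 15)
        p_welch = quant.compare_groups(a, b)

        def welch_t(x, y, axis):
            return stats.ttest_ind(x, y, equal_var=False, axis=axis).statistic

        perm = stats.permutation_test(
            (a, b), welch_t, permutation_type="independent",
            alternative="two-sided", n_resamples=100_000, rng=1,
        )
        assert p_welch == pytest.approx(perm.pvalue, abs=0.02)

    def test_short_group_rejected(self):
        with pytest.raises(ValueError):
            quant.compare_groups([1.0], [1.0, 2.0])


class TestTimecourse:
    def _series(self, values, timepoints=(24, 48, 72)):
        return pd.DataFrame(
            {
                "strain": "s",
                "compound": "1",
                "timepoint_h": timepoints,
                "value": values,
            }
        )

    def test_plateauing_series_stagnates(self):
        out = quant.timecourse_summary(self._series([40.0, 43.0, 43.8]))
        assert bool(out["stagnated"].iloc[0]) is True
        assert out["final_value"].iloc[0] == pytest.approx(43.8)

    def test_doubling_series_does_not_stagnate(self):
        out = quant.timecourse_summary(self._series([20.0, 40.0, 80.0]))
        assert bool(out["stagnated"].iloc[0]) is False

    def test_threshold_arithmetic(self):
        # final increase of 5 on a final value of 100: flagged below 5%/above 6%
        series = self._series([90.0, 95.0, 100.0])
        loose = quant.timecourse_summary(series, threshold=0.06)
        tight = quant.timecourse_summary(series, threshold=0.04)
        assert bool(loose["stagnated"].iloc[0]) is True
        assert bool(tight["stagnated"].iloc[0]) is False

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError, match="timepoints"):
            quant.timecourse_summary(self._series([1.0], timepoints=(72,)))
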