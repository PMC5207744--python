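"""Creep calibration: MSE objective, coverage, parameter recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import meatshift as ms
from meatshift.calibration import (
    CalibrationTargets,
    calibrate_increment,
    check_fit_coverage,
    mse,
)
from meatshift.engine import run_scenario
from meatshift.fixtures import make_targets
from meatshift.params import ParameterError, Scenario


class TestMse:
    def test_zero_iff_coincident(self):
        s = np.array([0.3, 0.4])
        assert mse(s, s) == 0.0
        assert mse(s, s + 0.01) > 0.0

    def test_single_point(self):
        assert mse([0.40], [0.35]) == pytest.approx(0.0025)

    def test_two_point_mean(self):
        assert mse([0.5, 0.3], [0.4, 0.3]) == pytest.approx(0.005)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse([0.1, 0.2], [0.1])


class TestCoverage:
    def make_targets(self, n=4):
        return CalibrationTargets(
            pd.DataFrame(
                {
                    "year": [2000, 2001] * (n // 2),
                    "subgroup": ["white_male"] * n,
                    "threshold": [25.0, 30.0] * (n // 2),
                    "prevalence": [0.5] * n,
                    "ci_low": [0.45] * n,
                    "ci_high": [0.55] * n,
                }
            ),
            start_year=2000,
        )

    def test_all_inside(self):
        assert check_fit_coverage([0.5] * 4, self.make_targets()) == 1.0

    def test_none_inside(self):
        assert check_fit_coverage([0.9] * 4, self.make_targets()) == 0.0

    def test_counting(self):
        assert check_fit_coverage([0.5, 0.5, 0.5, 0.9], self.make_targets()) == 0.75

    def test_requires_cis(self):
        t = self.make_targets()
        t2 = CalibrationTargets(
            t.df.drop(columns=["ci_low", "ci_high"]), start_year=2000
        )
        with pytest.raises(ValueError, match="confidence"):
            check_fit_coverage([0.5] * 4, t2)


class TestTargetValidation:
    def test_prevalence_bounds(self):
        with pytest.raises(ParameterError):
            CalibrationTargets(
                pd.DataFrame(
                    {
                        "year": [2000, 2001],
                        "subgroup": ["white_male"] * 2,
                        "threshold": [25.0] * 2,
                        "prevalence": [0.5, 1.4],
                    }
                ),
                start_year=2000,
            )

    def test_needs_two_years(self):
        with pytest.raises(ParameterError, match="fewer than 2"):
            CalibrationTargets(
                pd.DataFrame(
                    {
                        "year": [2000],
                        "subgroup": ["white_male"],
                        "threshold": [25.0],
                        "prevalence": [0.5],
                    }
                ),
                start_year=2000,
            )

    def test_unknown_threshold(self):
        with pytest.raises(ParameterError, match="threshold"):
            CalibrationTargets(
                pd.DataFrame(
                    {
                        "year": [2000, 2001],
                        "subgroup": ["white_male"] * 2,
                        "threshold": [27.0] * 2,
                        "prevalence": [0.5, 0.5],
                    }
                ),
                start_year=2000,
            )

    def test_round_trip_with_meta(self, tmp_path, params, demographics, life_table):
        df, meta = make_targets(
            params, demographics, life_table, seed=0, n=500, subgroups=("white_male",)
        )
        t = CalibrationTargets(df, start_year=1999, meta=meta)
        path = tmp_path / "targets.csv"
        t.to_csv(path)
        back = CalibrationTargets.from_csv(path)
        assert back.start_year == 1999
        assert "generating_increments" in back.meta
        pd.testing.assert_frame_equal(back.df, t.df)


class TestRecovery:
    def test_null_increment_recovered(self, params, demographics, life_table):
        zero_params = dataclasses.replace(
            params,
            subgroups={
                k: dataclasses.replace(sp, yearly_kcal_increase=0.0)
                for k, sp in params.subgroups.items()
            },
        )
        df, _ = make_targets(
            zero_params, demographics, life_table, seed=5, n=8_000,
            subgroups=("white_female",),
        )
        targets = CalibrationTargets(df, start_year=1999)
        res = calibrate_increment(
            targets, zero_params, demographics, life_table,
            search=(0.0, 4.0, 0.5), seed=6, n=8_000, subgroups=("white_female",),
        )
        assert res["white_female"].increment == 0.0

    def test_published_increment_recovered(self, params, demographics, life_table):
        """Self-consistency: targets generated at 12.3 kcal/yr for black
        males are recovered to within one 0.5 kcal/yr grid step (median
        over seeds — any single target realization carries binomial
        noise of the same order as one step)."""
        errors = []
        for seed in (0, 1, 2):
            df, _ = make_targets(
                params, demographics, life_table, seed=seed, n=20_000,
                subgroups=("black_male",),
            )
            targets = CalibrationTargets(df, start_year=1999)
            res = calibrate_increment(
                targets, params, demographics, life_table,
                search=(8.0, 16.0, 0.5), seed=seed + 100, n=20_000,
                subgroups=("black_male",),
            )
            errors.append(abs(res["black_male"].increment - 12.3))
        assert np.median(errors) <= 0.5 + 1e-9

    def test_monotone_mechanism(self, params, demographics, life_table):
        """End-of-window overweight prevalence rises with the increment."""
        demo_g = demographics.restrict("white", "male")
        cohort = ms.sample_population(5_000, demo_g, params, seed=1)
        prevs = []
        for inc in (0.0, 10.0, 20.0):
            p = dataclasses.replace(
                params,
                subgroups={
                    **params.subgroups,
                    "white_male": dataclasses.replace(
                        params.subgroups["white_male"], yearly_kcal_increase=inc
                    ),
                },
            )
            res = run_scenario(
                cohort,
                Scenario(price_change=0.0, horizon_years=13, n_individuals=5_000, seed=1),
                p,
                life_table,
            )
            rec = res.table[(res.table.year == 13) & (res.table.subgroup == "white_male")]
            prevs.append(float(rec.thr25.iloc[0]))
        assert prevs[0] < prevs[1] < prevs[2]

    def test_flat_profile_warns(self, params, demographics, life_table):
        """Targets from a tiny cohort over a short window cannot separate
        nearby increments: ties must be reported, and break low."""
        df, _ = make_targets(
            params, demographics, life_table, seed=3, n=60,
            subgroups=("white_male",), start_year=1999, end_year=2001,
        )
        targets = CalibrationTargets(df, start_year=1999)
        with pytest.warns(UserWarning, match="tie|flat"):
            res = calibrate_increment(
                targets, params, demographics, life_table,
                search=(0.0, 0.2, 0.1), seed=3, n=60, subgroups=("white_male",),
            )
        assert res["white_male"].increment in (0.0, 0.1, 0.2)
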