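"""Annual-cycle engine: determinism, conservation, CRN contrasts."""

import numpy as np
import pandas as pd
import pytest

import meatshift as ms
from meatshift.engine import contrast_vs_status_quo, obesity_prevalence, run_scenario
from meatshift.params import Demographics, SUBGROUPS


def scenario(price=0.0, seed=11, n=5_000, **kw):
    return ms.Scenario(price_change=price, seed=seed, n_individuals=n, **kw)


@pytest.fixture(scope="module")
def status_quo(cohort_small, params, life_table):
    return run_scenario(cohort_small, scenario(0.0), params, life_table)


@pytest.fixture(scope="module")
def fifty_percent(cohort_small, params, life_table):
    return run_scenario(cohort_small, scenario(0.50), params, life_table)


class TestDeterminism:
    def test_identical_runs_bit_identical(self, cohort_small, params, life_table, status_quo):
        again = run_scenario(cohort_small, scenario(0.0), params, life_table)
        pd.testing.assert_frame_equal(again.table, status_quo.table)
        assert np.array_equal(again.life_years, status_quo.life_years)
        assert np.array_equal(again.final_bmi, status_quo.final_bmi)


class TestConservation:
    def test_living_minus_deaths(self, status_quo):
        for key in SUBGROUPS:
            sub = status_quo.table[status_quo.table.subgroup == key].sort_values("year")
            living = sub.living.to_numpy()
            deaths = sub.deaths.to_numpy()
            assert np.all(living[1:] == living[:-1] - deaths[1:])

    def test_band_counts_sum_to_living(self, status_quo):
        t = status_quo.table
        bands = t[["underweight", "normal", "overweight", "obese"]].sum(axis=1)
        assert np.all(bands.to_numpy() == t.living.to_numpy())

    def test_person_time_bounds(self, status_quo, cohort_small):
        assert status_quo.life_years.sum() <= cohort_small.n * 15
        assert np.all(status_quo.qalys <= status_quo.life_years + 1e-12)
        cum = status_quo.table.groupby("subgroup").cum_life_years.apply(
            lambda s: np.all(np.diff(s.to_numpy()) >= 0)
        )
        assert cum.all()

    def test_t0_prevalence_matches_cohort(self, status_quo, cohort_small):
        for g, key in enumerate(SUBGROUPS):
            mask = cohort_small.subgroup == g
            expected = np.mean(cohort_small.bmi[mask] >= 30.0)
            assert obesity_prevalence(status_quo, 0, key) == pytest.approx(expected)


class TestBaselineFixedPoint:
    def test_zero_shock_zero_creep_is_static(self, cohort_small, params, life_table):
        res = run_scenario(
            cohort_small, scenario(0.0, creep_multiplier=0.0), params, life_table
        )
        assert np.max(np.abs(res.final_bmi - cohort_small.bmi)) < 1e-9

    def test_status_quo_mean_bmi_drift_is_creep_only(self, status_quo, cohort_small):
        # under the base-case creep the 15-year drift is positive but modest
        t = status_quo.table
        for key in SUBGROUPS:
            sub = t[t.subgroup == key]
            m0 = sub[sub.year == 0].mean_bmi.iloc[0]
            m15 = sub[sub.year == 15].mean_bmi.iloc[0]
            assert 0 < m15 - m0 < 4.0


class TestCommonRandomNumbers:
    def test_per_individual_bmi_monotone_in_price(self, status_quo, fifty_percent):
        assert np.all(fifty_percent.final_bmi <= status_quo.final_bmi + 1e-9)

    def test_self_contrast_is_zero(self, cohort_small, params, life_table, status_quo):
        again = run_scenario(cohort_small, scenario(0.0), params, life_table)
        c = contrast_vs_status_quo(again, status_quo)
        deltas = c[["delta_obesity_prev", "delta_ly_per_1000", "delta_qaly_per_1000"]]
        assert np.allclose(deltas.to_numpy(), 0.0)

    def test_contrast_rejects_mismatched_seeds(self, cohort_small, params, life_table, status_quo):
        other = run_scenario(cohort_small, scenario(0.25, seed=99), params, life_table)
        with pytest.raises(ValueError, match="seed"):
            contrast_vs_status_quo(other, status_quo)

    def test_ly_delta_is_arithmetic_identity(self, status_quo, fifty_percent, cohort_small):
        c = contrast_vs_status_quo(fifty_percent, status_quo)
        row = c[(c.subgroup == "white_male") & (c.stratum == "all")].iloc[0]
        mask = cohort_small.subgroup == 0
        expected = (
            (fifty_percent.life_years[mask].sum() - status_quo.life_years[mask].sum())
            / mask.sum()
            * 1000
        )
        assert row.delta_ly_per_1000 == pytest.approx(expected)

    def test_flat_mortality_isolates_bmi_channel(self, cohort_small, params, life_table):
        """With the BMI-mortality link switched off, survival no longer
        depends on weight, so life-years are identical across prices."""
        sq = run_scenario(
            cohort_small, scenario(0.0, flat_mortality_curve=True), params, life_table
        )
        hi = run_scenario(
            cohort_small, scenario(0.50, flat_mortality_curve=True), params, life_table
        )
        assert np.array_equal(sq.life_years, hi.life_years)


class TestPrevalence:
    def test_all_obese_cohort(self, params, life_table):
        import dataclasses

        demo = Demographics(
            pd.DataFrame({"age": [40], "sex": ["female"], "race": ["black"], "weight": [1.0]}),
            require_all_subgroups=False,
        )
        obese_params = dataclasses.replace(
            params,
            subgroups={
                **params.subgroups,
                "black_female": dataclasses.replace(
                    params.subgroups["black_female"], bmi_band_probs=(0.0, 0.0, 0.0, 1.0)
                ),
            },
        )
        cohort = ms.sample_population(300, demo, obese_params, seed=3)
        res = run_scenario(
            cohort, scenario(0.0, seed=3, n=300), obese_params, life_table
        )
        assert obesity_prevalence(res, 0, "black_female") == 1.0

    def test_missing_record_rejected(self, status_quo):
        with pytest.raises(ValueError):
            obesity_prevalence(status_quo, 99, "white_male")

    def test_initial_cohort_denominator(self, status_quo):
        living = obesity_prevalence(status_quo, 15, "white_male")
        initial = obesity_prevalence(status_quo, 15, "white_male", denominator="initial")
        assert initial <= living   # same numerator, never-shrinking denominator
        with pytest.raises(ValueError):
            obesity_prevalence(status_quo, 15, "white_male", denominator="bogus")
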