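import numpy as np
import pytest

import oaburden as ob
from oaburden.errors import DomainError, ParameterError
from oaburden.strata import ETHNICITIES, SEXES, Stratum, extended_bands

STRATUM = Stratum("40–44", "male", "non_maori")
OLD_STRATUM = Stratum("75–79", "female", "non_maori")


def constant_life_table(p5: float, closure_age: int = 110) -> ob.LifeTable:
    bands = extended_bands(closure_age)
    entries = {
        (eth, sex, b): (1.0 if b == bands[-1] else p5)
        for eth in ETHNICITIES
        for sex in SEXES
        for b in bands
    }
    return ob.LifeTable(entries=entries, closure_age=closure_age)


def constant_utilities(u: float) -> ob.UtilityTable:
    return ob.UtilityTable(
        values={(b, lv): u for b in ob.AGE_BANDS for lv in ob.PainLevel}, value_set="vas"
    )


def no_background_pain() -> ob.NonOAPainCurve:
    return ob.NonOAPainCurve(p_in_pain={b: 0.0 for b in ob.AGE_BANDS})


class TestAnnualMortality:
    @pytest.mark.parametrize("p5,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_boundary_values(self, p5, expected):
        assert ob.annual_mortality(p5) == expected

    def test_inverts_five_year_compounding(self):
        p1 = ob.annual_mortality(0.226)
        assert p1 == pytest.approx(1 - 0.774**0.2)
        assert 1 - (1 - p1) ** 5 == pytest.approx(0.226)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            ob.annual_mortality(1.2)


class TestSimulateIndividual:
    def test_certain_death_accrues_exactly_one_year(self):
        tables = ob.ModelTables(constant_utilities(0.8), constant_life_table(1.0), no_background_pain())
        q = ob.simulate_individual(42, STRATUM, ob.NO_OA, tables, ob.PainModelParams(), rng=0)
        assert q == pytest.approx(0.8)

    def test_zero_mortality_accrues_full_horizon(self):
        closure = 90
        tables = ob.ModelTables(
            constant_utilities(0.7), constant_life_table(0.0, closure), no_background_pain()
        )
        q = ob.simulate_individual(80, Stratum("80–84", "female", "non_maori"),
                                   ob.NO_OA, tables, ob.PainModelParams(), rng=0)
        assert q == pytest.approx((closure - 80) * 0.7)

    def test_deterministic_pain_matches_closed_form_exactly(self, utilities):
        # With zero mortality noise (p5 = 0) and a deterministic WOMAC path
        # the simulator is fully deterministic and must equal the oracle.
        tables = ob.ModelTables(utilities, constant_life_table(0.0, 100), no_background_pain())
        params = ob.PainModelParams(init_sd=0.0, annual_increment_sd=0.0)

        def level_at(age):
            womac = min(100.0, 30.0 + 0.5 * (age - 42))
            return ob.categorize_pain(womac)

        sim = ob.simulate_individual(42, STRATUM, ob.OA, tables, params, rng=0)
        oracle = ob.qale_closed_form(42, STRATUM, level_at, tables)
        assert sim == pytest.approx(oracle, abs=1e-9)


class TestClosedForm:
    def test_zero_mortality_constant_utility(self):
        tables = ob.ModelTables(
            constant_utilities(1.0), constant_life_table(0.0, 90), no_background_pain()
        )
        s = Stratum("80–84", "male", "maori")
        assert ob.qale_closed_form(80, s, ob.PainLevel.NONE, tables) == pytest.approx(10.0)

    def test_constant_hazard_matches_geometric_series(self):
        q = 0.2
        p5 = 1 - (1 - q) ** 5
        closure = 110
        tables = ob.ModelTables(
            constant_utilities(0.75), constant_life_table(p5, closure), no_background_pain()
        )
        got = ob.qale_closed_form(42, STRATUM, ob.PainLevel.NONE, tables)
        horizon = closure - 42
        expected = 0.75 * sum((1 - q) ** t for t in range(horizon))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_simulator_converges_to_closed_form(self, utilities):
        # Deterministic pain, stochastic mortality: the cohort mean must sit
        # within 4 Monte Carlo standard errors of the analytic expectation.
        life = ob.generate_life_table()
        tables = ob.ModelTables(utilities, life, no_background_pain())
        params = ob.PainModelParams(init_sd=0.0, annual_increment_sd=0.0)

        def level_at(age):
            return ob.categorize_pain(min(100.0, 30.0 + 0.5 * (age - 62)))

        s = Stratum("60–64", "female", "maori")
        res = ob.simulate_cohort(s, ob.OA, 20_000, tables, params, seed=77, start_age=62)
        oracle = ob.qale_closed_form(62, s, level_at, tables)
        assert abs(res.mean_qalys - oracle) < 4 * res.se_qalys


class TestSimulateCohort:
    def test_single_individual_has_zero_se(self, model_tables):
        res = ob.simulate_cohort(STRATUM, ob.OA, 1, model_tables, ob.PainModelParams(), seed=5)
        assert res.se_qalys == 0.0
        assert res.n_simulated == 1

    def test_se_shrinks_like_root_n(self, model_tables):
        params = ob.PainModelParams()
        r1 = ob.simulate_cohort(STRATUM, ob.OA, 2000, model_tables, params, seed=9)
        r2 = ob.simulate_cohort(STRATUM, ob.OA, 8000, model_tables, params, seed=9)
        ratio = r1.se_qalys / r2.se_qalys
        assert 1.6 < ratio < 2.5  # expect ~2 for a 4x sample

    def test_oa_cohort_never_beats_matched_no_oa_cohort(self, model_tables):
        params = ob.PainModelParams()
        for s in [STRATUM, OLD_STRATUM, Stratum("60–64", "male", "maori")]:
            oa = ob.simulate_cohort(s, ob.OA, 2000, model_tables, params, seed=21)
            no = ob.simulate_cohort(s, ob.NO_OA, 2000, model_tables, params, seed=21)
            assert oa.mean_qalys <= no.mean_qalys

    def test_fixed_seed_reproducible_and_order_independent(self, model_tables):
        params = ob.PainModelParams()
        a = ob.simulate_cohort_qalys(STRATUM, ob.OA, 500, model_tables, params, seed=3)
        # interleave another stratum's simulation: must not perturb the first
        ob.simulate_cohort_qalys(OLD_STRATUM, ob.NO_OA, 500, model_tables, params, seed=3)
        b = ob.simulate_cohort_qalys(STRATUM, ob.OA, 500, model_tables, params, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_qalys_bounded_by_years_lived(self, model_tables):
        qalys, years = ob.simulate_cohort_qalys(
            OLD_STRATUM, ob.NO_OA, 2000, model_tables, ob.PainModelParams(), seed=13,
            return_years=True,
        )
        assert np.all(qalys >= 0.0)
        assert np.all(qalys <= years + 1e-12)
        assert years.max() <= model_tables.life_table.closure_age - OLD_STRATUM.midpoint_age

    def test_raising_utilities_raises_every_individual(self, utilities, life_table, pain_curve):
        params = ob.PainModelParams()
        base = ob.ModelTables(utilities, life_table, pain_curve)
        bumped_vals = {k: min(1.0, v + 0.01) for k, v in utilities.values.items()}
        bumped = ob.ModelTables(
            ob.UtilityTable(values=bumped_vals, value_set="vas"), life_table, pain_curve
        )
        q0 = ob.simulate_cohort_qalys(STRATUM, ob.OA, 1000, base, params, seed=17)
        q1 = ob.simulate_cohort_qalys(STRATUM, ob.OA, 1000, bumped, params, seed=17)
        assert np.all(q1 >= q0 - 1e-12)

    def test_survival_matches_life_table_within_binomial_error(self, model_tables):
        n = 5000
        _, years = ob.simulate_cohort_qalys(
            STRATUM, ob.NO_OA, n, model_tables, ob.PainModelParams(), seed=29,
            return_years=True,
        )
        s_curve = ob.survival_curve(model_tables.life_table, STRATUM.ethnicity, STRATUM.sex)
        offset = STRATUM.midpoint_age - 40
        for t in (5, 15, 30):
            p = s_curve[offset + t] / s_curve[offset]
            observed = np.mean(years > t)
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) < 4 * sigma + 1e-9

    def test_individual_and_cohort_paths_agree_statistically(self, model_tables):
        params = ob.PainModelParams(init_sd=0.0, annual_increment_sd=0.0)
        cohort = ob.simulate_cohort(STRATUM, ob.OA, 20_000, model_tables, params, seed=31)
        n_ind = 2000
        rng = np.random.default_rng(101)
        singles = np.array([
            ob.simulate_individual(42, STRATUM, ob.OA, model_tables, params, rng)
            for _ in range(n_ind)
        ])
        se = np.sqrt(cohort.se_qalys**2 + singles.var(ddof=1) / n_ind)
        assert abs(singles.mean() - cohort.mean_qalys) < 4 * se

    @pytest.mark.parametrize("bad_n", [0, -5])
    def test_invalid_cohort_size_rejected(self, model_tables, bad_n):
        with pytest.raises(ParameterError):
            ob.simulate_cohort(STRATUM, ob.OA, bad_n, model_tables, ob.PainModelParams(), seed=1)
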