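import numpy as np
import pandas as pd
import pytest

import oaburden as ob
from oaburden.burden import TOTAL, group_losses
from oaburden.errors import (
    AlignmentError,
    CompletenessError,
    DegenerateDistributionError,
    DomainError,
)
from oaburden.published import strata_frame, summary_frame
from oaburden.strata import AGE_BANDS, GROUPS, STRATA, Stratum


def uniform_population(count: int) -> ob.PopulationCounts:
    return ob.PopulationCounts(counts={s: count for s in STRATA})


def uniform_prevalence(p: float) -> ob.PrevalenceTable:
    return ob.PrevalenceTable(values={s: p for s in STRATA})


class TestOAAgeDistribution:
    def test_uniform_inputs_give_uniform_weights(self):
        w = ob.oa_age_distribution(uniform_prevalence(0.1), uniform_population(100),
                                   "non_maori", "male")
        assert all(v == pytest.approx(1 / 9) for v in w.values())

    def test_single_prevalent_band_takes_all_weight(self):
        values = {s: (0.2 if s.age_band == "60–64" else 0.0) for s in STRATA}
        prev = ob.PrevalenceTable(values=values)
        w = ob.oa_age_distribution(prev, uniform_population(50), "maori", "female")
        assert w["60–64"] == 1.0
        assert sum(w.values()) == pytest.approx(1.0)

    def test_matches_direct_arithmetic(self, prevalence):
        counts = {s: int(1000 * 0.9 ** AGE_BANDS.index(s.age_band)) for s in STRATA}
        pop = ob.PopulationCounts(counts=counts)
        w = ob.oa_age_distribution(prevalence, pop, "non_maori", "female")
        raw = np.array([
            prevalence.prevalence(Stratum(b, "female", "non_maori"))
            * counts[Stratum(b, "female", "non_maori")]
            for b in AGE_BANDS
        ])
        expected = raw / raw.sum()
        np.testing.assert_allclose([w[b] for b in AGE_BANDS], expected, rtol=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            ob.oa_age_distribution(uniform_prevalence(0.0), uniform_population(10),
                                   "maori", "male")


class TestCounterfactualQale:
    def test_point_mass_returns_that_band(self):
        qale = {b: float(i) for i, b in enumerate(AGE_BANDS)}
        assert ob.counterfactual_qale(qale, {"60–64": 1.0}) == 4.0

    def test_constant_qale_invariant_to_weights(self):
        qale = {b: 17.3 for b in AGE_BANDS}
        w = {b: 1 / 9 for b in AGE_BANDS}
        assert ob.counterfactual_qale(qale, w) == pytest.approx(17.3)

    def test_matches_dot_product(self):
        rng = np.random.default_rng(0)
        qale = {b: float(q) for b, q in zip(AGE_BANDS, rng.uniform(5, 30, 9))}
        raw = rng.uniform(0, 1, 9)
        w = {b: float(x) for b, x in zip(AGE_BANDS, raw / raw.sum())}
        expected = float(np.dot([qale[b] for b in AGE_BANDS], [w[b] for b in AGE_BANDS]))
        assert ob.counterfactual_qale(qale, w) == pytest.approx(expected, rel=1e-12)

    def test_band_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            ob.counterfactual_qale({"40–44": 10.0}, {"45–49": 1.0})


class TestScalarLosses:
    @pytest.mark.parametrize(
        "cf,oa,expected",
        [(28.82, 22.34, 6.48), (15.54, 12.20, 3.34), (7.0, 7.0, 0.0)],
    )
    def test_per_person_loss(self, cf, oa, expected):
        assert ob.per_person_loss(cf, oa) == pytest.approx(expected, abs=0.01)

    def test_population_loss_direct_product(self):
        assert ob.population_loss(2.0, 0.1, 1000) == pytest.approx(200.0)
        assert ob.population_loss(5.0, 0.0, 1000) == 0.0

    def test_population_loss_rejects_bad_inputs(self):
        with pytest.raises(DomainError):
            ob.population_loss(1.0, 1.5, 10)
        with pytest.raises(DomainError):
            ob.population_loss(1.0, 0.5, -1)

    def test_proportion_lost_published_rows(self):
        assert ob.proportion_lost(3.34, 15.54) == pytest.approx(0.215, abs=0.001)
        assert ob.proportion_lost(2.60, 12.64) == pytest.approx(0.2057, abs=0.0005)
        assert ob.proportion_lost(0.0, 12.0) == 0.0

    def test_proportion_lost_rejects_zero_denominator(self):
        with pytest.raises(DomainError):
            ob.proportion_lost(1.0, 0.0)


class TestBuildBurdenTables:
    def constant_results(self, no_oa=20.0, oa=15.0):
        return {
            (s, status): (no_oa if status == ob.NO_OA else oa)
            for s in STRATA
            for status in (ob.OA, ob.NO_OA)
        }

    def test_identical_qale_everywhere_gives_flat_losses(self):
        frame = ob.build_burden_tables(
            self.constant_results(), uniform_prevalence(0.1), uniform_population(100)
        )
        assert np.allclose(frame.per_person_loss, 5.0)
        total = frame[(frame.ethnicity == "all") & (frame.age_band == TOTAL)]
        assert total.per_person_loss.iloc[0] == pytest.approx(5.0)

    def test_missing_stratum_reported(self):
        results = self.constant_results()
        missing_key = (Stratum("60–64", "male", "maori"), ob.OA)
        del results[missing_key]
        with pytest.raises(CompletenessError, match="60–64"):
            ob.build_burden_tables(results, uniform_prevalence(0.1), uniform_population(100))

    def test_grand_total_is_sum_of_group_totals(self, burden_frame):
        groups = burden_frame[
            (burden_frame.age_band == TOTAL) & (burden_frame.ethnicity != "all")
        ]
        grand = burden_frame[(burden_frame.ethnicity == "all")]
        assert grand.population_loss.iloc[0] == pytest.approx(groups.population_loss.sum())
        assert grand.n_with_oa.iloc[0] == pytest.approx(groups.n_with_oa.sum())

    def test_group_totals_aggregate_band_rows(self, burden_frame):
        for eth, sex in GROUPS:
            bands = burden_frame[
                (burden_frame.ethnicity == eth) & (burden_frame.sex == sex)
                & (burden_frame.age_band != TOTAL)
            ]
            group = burden_frame[
                (burden_frame.ethnicity == eth) & (burden_frame.sex == sex)
                & (burden_frame.age_band == TOTAL)
            ]
            assert group.population_loss.iloc[0] == pytest.approx(bands.population_loss.sum())
            # per-person × cases identity at every aggregation level
            assert group.population_loss.iloc[0] == pytest.approx(
                group.per_person_loss.iloc[0] * group.n_with_oa.iloc[0]
            )

    def test_rows_satisfy_loss_identity(self, burden_frame):
        np.testing.assert_allclose(
            burden_frame.per_person_loss,
            burden_frame.qale_counterfactual - burden_frame.qale_oa,
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            burden_frame.population_loss,
            burden_frame.per_person_loss * burden_frame.n_with_oa,
            rtol=1e-12,
        )

    def test_losses_non_negative_under_utility_ordering(self, burden_frame):
        assert (burden_frame.per_person_loss >= 0).all()
        assert (burden_frame.population_loss >= 0).all()

    def test_result_invariant_to_input_ordering(self, pipeline_inputs):
        results = ob.simulate_all_cohorts(pipeline_inputs)
        shuffled = dict(reversed(list(results.items())))
        a = ob.build_burden_tables(results, pipeline_inputs.prevalence,
                                   pipeline_inputs.population)
        b = ob.build_burden_tables(shuffled, pipeline_inputs.prevalence,
                                   pipeline_inputs.population)
        pd.testing.assert_frame_equal(a, b)

    def test_doubling_prevalence_doubles_population_losses(self, pipeline_inputs):
        results = ob.simulate_all_cohorts(pipeline_inputs)
        base = ob.build_burden_tables(results, pipeline_inputs.prevalence,
                                      pipeline_inputs.population)
        doubled = ob.build_burden_tables(
            results, pipeline_inputs.prevalence.scaled(2.0), pipeline_inputs.population
        )
        bands = base.age_band != TOTAL
        np.testing.assert_allclose(
            doubled.population_loss[bands], 2.0 * base.population_loss[bands], rtol=1e-12
        )
        # band-level per-person losses do not depend on prevalence at all
        np.testing.assert_allclose(
            doubled.per_person_loss[bands], base.per_person_loss[bands], rtol=1e-12
        )


class TestPublishedTableArithmetic:
    """Feed published QALE columns through the burden operations."""

    def test_band_loss_columns_reproduced(self):
        frame = strata_frame()
        recomputed = frame.qale_no_oa - frame.qale_oa
        assert np.all(np.abs(recomputed - frame.per_person_loss) <= 0.01 + 1e-9)

    def test_summary_loss_column_reproduced(self):
        frame = summary_frame()
        recomputed = frame.qale_counterfactual - frame.qale_oa
        assert np.all(np.abs(recomputed - frame.per_person_loss) <= 0.01 + 1e-9)

    def test_proportion_lost_within_published_range(self):
        frame = summary_frame()
        props = (frame.qale_counterfactual - frame.qale_oa) / frame.qale_counterfactual
        assert props.between(0.20, 0.23).all()


def test_group_losses_helper(burden_frame):
    losses = group_losses(burden_frame)
    assert set(losses) == {
        "non_maori_male", "non_maori_female", "maori_male", "maori_female", "overall",
    }
    assert all(v > 0 for v in losses.values())
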