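import math

import numpy as np
import pytest
from scipy.special import expit

from adrsignal.cohort import CYP_FLAGS
from adrsignal.synthetic import (
    CohortSpec,
    TrueEffects,
    assign_outcomes,
    build_drug_catalog,
    reference_fixture,
    sample_cohort,
)


class TestDrugCatalog:
    def test_degenerate_single_plain_drug(self):
        spec = CohortSpec(n_cases=10, n_repeat_visits=0, n_missing_medication=0,
                          catalog_size=1, combination_fraction=0,
                          unspecific_fraction=0, supplement_fraction=0,
                          cyp_flag_prob=0, seed=1)
        cat = build_drug_catalog(spec, spec.rng())
        assert len(cat) == 1
        row = cat.table.iloc[0]
        assert "/" not in row.drug_name
        assert not row.is_combination and not row.is_unspecific and not row.is_supplement
        assert not any(row[f] for f in CYP_FLAGS)

    def test_seeded_determinism(self):
        spec = CohortSpec(n_cases=50, n_repeat_visits=5, n_missing_medication=1,
                          catalog_size=120, seed=9)
        a = build_drug_catalog(spec, spec.rng())
        b = build_drug_catalog(spec, spec.rng())
        assert a.table.equals(b.table)

    def test_default_catalog_has_1627_distinct_names(self):
        spec = CohortSpec(seed=2)
        cat = build_drug_catalog(spec, spec.rng())
        assert len(cat) == 1627
        assert cat.table["drug_name"].nunique() == 1627

    def test_fraction_flags_present(self, small_catalog):
        t = small_catalog.table
        assert t.is_combination.sum() > 0
        assert all("/" in n for n in t.loc[t.is_combination, "drug_name"])

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(catalog_size=0)


class TestSampleCohort:
    def test_direct_count_contract(self):
        spec = CohortSpec(n_cases=3, n_repeat_visits=1, n_missing_medication=0,
                          catalog_size=10, seed=4)
        rng = spec.rng()
        cat = build_drug_catalog(spec, rng)
        coh = sample_cohort(spec, cat, rng)
        assert len(coh) == 3
        pids = [r.patient_id for r in coh]
        assert len(set(pids)) == 2  # one patient appears twice
        second = [r for r in coh if r.visit_index == 2]
        assert len(second) == 1
        assert any(r.patient_id == second[0].patient_id and r.visit_index == 1
                   for r in coh)

    def test_missing_medication_cases_are_first_visits(self, small_cohort):
        empty = [r for r in small_cohort if len(r.drugs) == 0]
        assert len(empty) == 2
        assert all(r.visit_index == 1 for r in empty)

    def test_no_duplicate_drugs_within_case(self, small_cohort):
        for rec in small_cohort:
            assert len(rec.drugs) == len(set(rec.drugs))

    def test_invalid_special_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_cases=5, n_repeat_visits=3, n_missing_medication=2)

    def test_seeded_determinism_byte_identical(self, small_spec, tmp_path):
        def render():
            rng = small_spec.rng()
            cat = build_drug_catalog(small_spec, rng)
            coh = sample_cohort(small_spec, cat, rng)
            return coh.case_frame().to_csv(), coh.exposure_frame().to_csv()

        assert render() == render()

    def test_calibration_of_default_marginals(self):
        """Defaults emulate the registry: median age 72 (58;81), median 7
        drugs per case (3;10), each within one unit on one seeded draw."""
        spec = CohortSpec(seed=123)
        rng = spec.rng()
        cat = build_drug_catalog(spec, rng)
        coh = sample_cohort(spec, cat, rng)
        ages = np.array([r.age for r in coh])
        q_age = np.percentile(ages, [25, 50, 75])
        assert abs(q_age[1] - 72) <= 2.5
        assert abs(q_age[0] - 58) <= 3 and abs(q_age[2] - 81) <= 3
        counts = np.array([len(r.drugs) for r in coh if r.drugs])
        q = np.percentile(counts, [25, 50, 75])
        assert abs(q[1] - 7) <= 1
        assert abs(q[0] - 3) <= 1 and abs(q[2] - 10) <= 1

    @pytest.mark.parametrize("exponent", [1.0, 1.2, 1.45])
    def test_zipf_rank_curve(self, exponent):
        """Drug frequency decreases with popularity rank and the Zipf
        exponent is recovered within 20% by log-log regression (mid-tail
        ranks; the head is flattened by without-replacement sampling)."""
        from scipy import stats

        spec = CohortSpec(n_cases=5000, n_repeat_visits=0, n_missing_medication=0,
                          catalog_size=500, zipf_exponent=exponent, seed=31)
        rng = spec.rng()
        cat = build_drug_catalog(spec, rng)
        coh = sample_cohort(spec, cat, rng)
        freq = np.zeros(len(cat))
        pos = {n: i for i, n in enumerate(cat.names)}
        for rec in coh:
            for d in rec.drugs:
                freq[pos[d]] += 1
        ranks = np.arange(1, len(cat) + 1)
        assert stats.spearmanr(ranks[:300], freq[:300]).statistic < -0.95
        sel = slice(19, 200)
        slope = np.polyfit(np.log(ranks[sel]), np.log(freq[sel]), 1)[0]
        assert abs(-slope - exponent) / exponent < 0.2


class TestAssignOutcomes:
    def _flat_cohort(self, n, seed=0):
        spec = CohortSpec(n_cases=n, n_repeat_visits=0, n_missing_medication=0,
                          catalog_size=30, seed=seed)
        rng = spec.rng()
        cat = build_drug_catalog(spec, rng)
        return cat, sample_cohort(spec, cat, rng), rng

    def test_null_model_gives_half_prevalence(self):
        cat, coh, rng = self._flat_cohort(10_000)
        coh = assign_outcomes(coh, TrueEffects(intercept=0.0), rng)
        prev = np.mean([r.outcome for r in coh])
        se = 0.5 / math.sqrt(10_000)
        assert abs(prev - 0.5) < 3 * se

    def test_rare_outcome_intercept(self):
        q = 455 / 7175
        cat, coh, rng = self._flat_cohort(10_000, seed=1)
        coh = assign_outcomes(
            coh, TrueEffects(intercept=math.log(455 / 6720)), rng)
        prev = np.mean([r.outcome for r in coh])
        se = math.sqrt(q * (1 - q) / 10_000)
        assert abs(prev - q) < 3 * se

    def test_planted_drug_effect_separates_rates(self):
        cat, coh, rng = self._flat_cohort(10_000, seed=2)
        drug = cat.names[0]  # most popular substance
        coh = assign_outcomes(
            coh, TrueEffects(intercept=-3.0, drug_effects={drug: 3.0}), rng)
        with_drug = [r.outcome for r in coh if drug in r.drugs]
        without = [r.outcome for r in coh if drug not in r.drugs]
        assert np.mean(with_drug) - np.mean(without) > 0.2

    def test_prevalence_matches_average_true_probability(self):
        cat, coh, rng = self._flat_cohort(10_000, seed=3)
        eff = TrueEffects(intercept=-1.0, covariate_effects={"sex_female": 0.5})
        from adrsignal.synthetic import linear_predictor

        target = float(np.mean(expit(linear_predictor(coh, eff))))
        coh = assign_outcomes(coh, eff, rng)
        prev = np.mean([r.outcome for r in coh])
        se = math.sqrt(target * (1 - target) / 10_000)
        assert abs(prev - target) < 3 * se

    def test_unknown_covariate_rejected(self):
        cat, coh, rng = self._flat_cohort(10, seed=4)
        eff = TrueEffects(intercept=0.0, covariate_effects={"n_cyp3a4_substrate": 1.0})
        with pytest.raises(KeyError):
            assign_outcomes(coh, eff, rng)

    def test_nonfinite_effect_rejected(self):
        with pytest.raises(ValueError):
            TrueEffects(intercept=float("nan"))


@pytest.fixture(scope="module")
def falls():
    return reference_fixture(seed=5, outcome="falls")


class TestReferenceFixture:
    def test_raw_case_count(self, falls):
        cohort, _, _ = falls
        assert len(cohort) == 7967

    def test_repeat_and_missing_structure(self, falls):
        cohort, _, _ = falls
        repeats = [r for r in cohort if r.visit_index == 2]
        assert len(repeats) == 791
        missing = [r for r in cohort if len(r.drugs) == 0]
        assert len(missing) == 1

    def test_exact_positive_count_among_survivors(self, falls):
        cohort, _, _ = falls
        from adrsignal.synthetic import _analysis_survivors

        surv = set(_analysis_survivors(cohort))
        assert len(surv) == 7175
        pos = sum(r.outcome for r in cohort if r.case_id in surv)
        assert pos == 455

    def test_planted_drugs_exist_in_catalog(self, falls):
        _, effects, catalog = falls
        assert set(effects.drug_effects) <= set(catalog.names)
        assert len(effects.drug_effects) == 5

    def test_bleeding_variant_count(self):
        cohort, _, _ = reference_fixture(seed=5, outcome="bleeding")
        from adrsignal.synthetic import _analysis_survivors

        surv = set(_analysis_survivors(cohort))
        pos = sum(r.outcome for r in cohort if r.case_id in surv)
        assert pos == 1977

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError):
            reference_fixture(seed=0, outcome="rash")
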