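import numpy as np
import pandas as pd
import pytest

from adrsignal.curation import (
    COVARIATE_NAMES,
    CurationConfig,
    CurationReport,
    DesignMatrix,
    annotate_cyp,
    assemble_design_matrix,
    count_excluded,
    curate,
    drop_missing_medication,
    drug_frequencies,
    keep_first_visits,
    normalize_drugs,
    select_top_drugs,
    _normalized_cohort,
)

from conftest import cohort_of, make_record


class TestVisitFilter:
    def test_keeps_earliest_visit(self):
        coh = cohort_of(make_record(1, patient_id=1, visit_index=1),
                        make_record(2, patient_id=1, visit_index=2))
        kept, removed = keep_first_visits(coh)
        assert removed == 1
        assert [r.case_id for r in kept] == [1]

    def test_identity_without_repeats(self):
        coh = cohort_of(make_record(1), make_record(2))
        kept, removed = keep_first_visits(coh)
        assert removed == 0 and len(kept) == 2

    def test_duplicate_patient_visit_rejected(self):
        coh = cohort_of(make_record(1, patient_id=1, visit_index=1),
                        make_record(2, patient_id=1, visit_index=1))
        with pytest.raises(ValueError, match="duplicate"):
            keep_first_visits(coh)


class TestMissingMedication:
    def test_drops_empty_lists(self):
        coh = cohort_of(make_record(1, drugs=()), make_record(2), make_record(3))
        kept, removed = drop_missing_medication(coh)
        assert removed == 1 and len(kept) == 2

    def test_identity_when_complete(self):
        coh = cohort_of(make_record(1), make_record(2))
        kept, removed = drop_missing_medication(coh)
        assert removed == 0 and len(kept) == 2


class TestNormalizeDrugs:
    def test_keep_main_substance(self, plain_config):
        assert normalize_drugs(["oxycodone/naloxone"], plain_config) == (["oxycodone"], 0)

    def test_unspecific_dropped_and_counted(self):
        cfg = CurationConfig(min_count=1, unspecific_names=frozenset({"NSAID"}))
        assert normalize_drugs(["NSAID"], cfg) == ([], 1)

    def test_plain_combination_split(self):
        cfg = CurationConfig(min_count=1, keep_main_substance={})
        assert normalize_drugs(["a/b"], cfg) == (["a", "b"], 0)

    def test_duplicates_collapse(self, plain_config):
        out, dropped = normalize_drugs(
            ["tilidine/naloxone", "tilidine", "aspirin"], plain_config)
        assert out == ["tilidine", "aspirin"] and dropped == 0

    def test_supplement_dropped(self):
        cfg = CurationConfig(min_count=1, supplement_names=frozenset({"calcium"}))
        assert normalize_drugs(["calcium", "aspirin"], cfg) == (["aspirin"], 1)

    def test_empty_name_rejected(self, plain_config):
        with pytest.raises(ValueError):
            normalize_drugs([""], plain_config)

    def test_keep_main_target_must_be_single(self):
        with pytest.raises(ValueError):
            CurationConfig(keep_main_substance={"a/b": "a/b"})

    def test_idempotent_on_normalized_list(self, plain_config):
        once, _ = normalize_drugs(["oxycodone/naloxone", "a/b", "x"], plain_config)
        twice, dropped = normalize_drugs(once, plain_config)
        assert twice == once and dropped == 0


def _freq_cohort(freqs):
    """Cohort in which drug d appears in exactly freqs[d] single-drug cases."""
    records, cid = [], 0
    for drug, count in freqs.items():
        for _ in range(count):
            cid += 1
            records.append(make_record(cid, drugs=(drug,)))
    return cohort_of(*records)


class TestSelectTopDrugs:
    def test_numeric_threshold(self):
        coh = _freq_cohort({"A": 50, "B": 40, "C": 31, "D": 10})
        cfg = CurationConfig(min_count=32, top_n=100)
        selected, threshold, _ = select_top_drugs(coh, cfg)
        assert selected == ["A", "B"] and threshold == 32

    def test_top_n_cap(self):
        coh = _freq_cohort({f"d{i:03d}": 5 + i for i in range(150)})
        cfg = CurationConfig(min_count=1, top_n=100)
        selected, _, _ = select_top_drugs(coh, cfg)
        assert len(selected) == 100
        freq = drug_frequencies(coh)
        floor = min(freq[d] for d in selected)
        assert all(freq[d] <= floor for d in freq if d not in selected)

    def test_alphabetical_tie_break(self):
        coh = _freq_cohort({"B": 40, "A": 40})
        selected, _, _ = select_top_drugs(coh, CurationConfig(min_count=1, top_n=1))
        assert selected == ["A"]

    def test_auto_knee_threshold(self):
        # 3 very common drugs and a long tail of singletons: the knee
        # criterion should keep only the common block
        freqs = {"A": 60, "B": 50, "C": 40}
        freqs.update({f"t{i:02d}": 1 for i in range(30)})
        coh = _freq_cohort(freqs)
        selected, threshold, diag = select_top_drugs(
            coh, CurationConfig(min_count="auto", top_n=100))
        assert set(selected) == {"A", "B", "C"}
        assert threshold > 1
        assert {"threshold", "coverage", "retained_fraction", "objective"} \
            <= set(diag.columns)

    def test_no_survivor_errors(self):
        coh = _freq_cohort({"A": 2})
        with pytest.raises(ValueError):
            select_top_drugs(coh, CurationConfig(min_count=5, top_n=10))


class TestCovariates:
    def test_count_excluded(self):
        assert count_excluded(list("abcdefghi"), list("abcdefg")) == 2
        assert count_excluded(["a", "b"], ["a", "b", "c"]) == 0

    def test_annotate_cyp_lookup(self):
        table = {"drugX": {"cyp3a4_substrate": True},
                 "drugY": {"cyp3a4_inhibitor": True}}
        counts = annotate_cyp(["drugX", "drugY"], table)
        assert counts["n_cyp3a4_substrate"] == 1
        assert counts["n_cyp3a4_inhibitor"] == 1
        assert sum(counts.values()) == 2

    def test_empty_list_all_zero(self):
        counts = annotate_cyp([], {"drugX": {"cyp2d6_substrate": True}})
        assert set(counts.values()) == {0}

    def test_dual_role_counts_once_each(self):
        table = {"z": {"cyp2c19_substrate": True, "cyp2c19_inhibitor": True}}
        counts = annotate_cyp(["z"], table)
        assert counts["n_cyp2c19_substrate"] == 1
        assert counts["n_cyp2c19_inhibitor"] == 1

    def test_unknown_drug_contributes_zero(self):
        counts = annotate_cyp(["mystery"], {})
        assert sum(counts.values()) == 0


class TestAssembleDesignMatrix:
    def test_indicator_row(self):
        coh = cohort_of(make_record(1, drugs=("a",)))
        dm, _ = assemble_design_matrix(coh, ["a", "b"], CurationConfig(min_count=1))
        assert list(dm.frame.loc[1, ["a", "b"]]) == [1, 0]

    def test_all_male_cohort_zero_sex_column(self):
        coh = cohort_of(make_record(1, sex="male"), make_record(2, sex="male"))
        dm, _ = assemble_design_matrix(coh, ["aspirin"], CurationConfig(min_count=1))
        assert (dm.frame["sex_female"] == 0).all()

    def test_column_accounting(self):
        coh = cohort_of(make_record(1), make_record(2))
        dm, _ = assemble_design_matrix(coh, ["aspirin"], CurationConfig(min_count=1))
        assert dm.column_names == ["aspirin", *COVARIATE_NAMES, "outcome"]

    def test_empty_selected_rejected(self):
        coh = cohort_of(make_record(1))
        with pytest.raises(ValueError):
            assemble_design_matrix(coh, [], CurationConfig(min_count=1))

    def test_missing_outcome_rejected(self):
        coh = cohort_of(make_record(1, outcome=None))
        with pytest.raises(ValueError, match="outcome"):
            assemble_design_matrix(coh, ["aspirin"], CurationConfig(min_count=1))

    def test_rows_sorted_by_case_id(self):
        coh = cohort_of(make_record(5), make_record(2), make_record(9))
        dm, _ = assemble_design_matrix(coh, ["aspirin"], CurationConfig(min_count=1))
        assert list(dm.case_ids) == [2, 5, 9]

    def test_csv_round_trip(self, tmp_path):
        coh = cohort_of(make_record(1, drugs=("a", "b")), make_record(2, drugs=("b",)))
        dm, _ = assemble_design_matrix(coh, ["a", "b"], CurationConfig(min_count=1))
        path = dm.to_csv(tmp_path / "dm.csv")
        back = DesignMatrix.from_csv(path)
        pd.testing.assert_frame_equal(back.frame, dm.frame, check_dtype=False)
        assert back.drug_names == dm.drug_names


class TestPipelineInvariants:
    def test_case_count_conservation(self, small_cohort, small_catalog):
        from adrsignal.pipeline import curation_config_from

        cfg = curation_config_from(small_catalog, {"min_count": 2, "top_n": 40})
        cohort = small_cohort.with_outcomes(
            {r.case_id: 0 for r in small_cohort})
        dm, report = curate(cohort, cfg)
        assert report.n_final + report.n_removed_repeat \
            + report.n_removed_missing_med == report.n_raw
        assert report.n_final == dm.shape[0]

    def test_report_conservation_enforced(self):
        with pytest.raises(ValueError):
            CurationReport(n_raw=10, n_removed_repeat=1, n_removed_missing_med=1,
                           n_final=9, n_substances_raw=5,
                           n_substances_after_threshold=5, selected_drugs=[])

    def test_selected_plus_excluded_is_normalized_count(self, small_cohort,
                                                        small_catalog):
        from adrsignal.pipeline import curation_config_from

        cfg = curation_config_from(small_catalog, {"min_count": 2, "top_n": 30})
        cohort, _ = keep_first_visits(small_cohort)
        cohort, _ = drop_missing_medication(cohort)
        normalized, _ = _normalized_cohort(cohort, cfg)
        selected, _, _ = select_top_drugs(normalized, cfg)
        sel = set(selected)
        for rec in normalized:
            taken = sum(1 for d in set(rec.drugs) if d in sel)
            assert taken + count_excluded(rec.drugs, sel) == len(set(rec.drugs))

    def test_indicator_column_sums_match_frequencies(self, small_cohort,
                                                     small_catalog):
        from adrsignal.pipeline import curation_config_from

        cfg = curation_config_from(small_catalog, {"min_count": 2, "top_n": 30})
        cohort = small_cohort.with_outcomes({r.case_id: 0 for r in small_cohort})
        cohort, _ = keep_first_visits(cohort)
        cohort, _ = drop_missing_medication(cohort)
        normalized, dropped = _normalized_cohort(cohort, cfg)
        selected, _, _ = select_top_drugs(normalized, cfg)
        dm, _ = assemble_design_matrix(normalized, selected, cfg,
                                       dropped_counts=dropped)
        freq = drug_frequencies(normalized)
        for drug in selected:
            assert dm.frame[drug].sum() == freq[drug]

    def test_stage_idempotence(self, small_cohort):
        # name lists empty here: a case whose drugs are all unspecific or
        # supplements is emptied by normalization yet must stay in the
        # analysis (the missing-record filter applies to raw records only),
        # so full-pipeline idempotence is stated for name-based stages
        cfg = CurationConfig(min_count=2, top_n=30)
        cohort, _ = keep_first_visits(small_cohort)
        cohort, _ = drop_missing_medication(cohort)
        normalized, _ = _normalized_cohort(cohort, cfg)

        again, r1 = keep_first_visits(normalized)
        again, r2 = drop_missing_medication(again)
        again, dropped = _normalized_cohort(again, cfg)
        assert r1 == 0 and r2 == 0
        assert all(d == 0 for d in dropped.values())
        assert [r.drugs for r in again] == [r.drugs for r in normalized]

    def test_cases_emptied_by_normalization_survive(self):
        cfg = CurationConfig(min_count=1, unspecific_names=frozenset({"NSAID"}))
        coh = cohort_of(make_record(1, drugs=("NSAID",)),
                        make_record(2, drugs=("aspirin",)))
        dm, report = curate(coh, cfg)
        assert report.n_final == 2
        assert dm.frame.loc[1, "n_excluded"] == 1
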