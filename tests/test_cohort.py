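"""Target-drug matching, demographics, and 2x2 contingency construction."""

import math

import numpy as np
import pandas as pd
import pytest

from pvsignal.cohort import (
    Cohort,
    build_cohort,
    build_contingency,
    contingency_all,
    count_concomitants,
    match_target_drug,
    normalize_age,
    summarize_cohort,
)


def _drugs(rows):
    return pd.DataFrame(
        rows, columns=["primaryid", "drug_seq", "name", "active_ingredient", "role"]
    )


class TestMatchTargetDrug:
    def test_matches_dictionary_entry_with_accepted_role(self):
        drugs = _drugs([(1, 1, "SORAFENIB", "", "PS")])
        assert match_target_drug(drugs, {"SORAFENIB"}, {"PS", "SS"}) == {1}

    def test_role_filter_excludes_concomitant_mention(self):
        drugs = _drugs([(1, 1, "sorafenib tosylate", "", "C")])
        assert match_target_drug(drugs, {"SORAFENIB TOSYLATE"}, {"PS", "SS"}) == set()

    def test_case_folding_and_whitespace_collapse(self):
        drugs = _drugs([(1, 1, "  sorafenib   Tosylate ", "", "SS")])
        assert match_target_drug(drugs, {"SORAFENIB TOSYLATE"}, {"PS", "SS"}) == {1}

    def test_empty_dictionary_is_configuration_error(self):
        with pytest.raises(ValueError):
            match_target_drug(_drugs([]), set(), {"PS"})

    def test_synthetic_matches_manifest(self, small_dataset, small_data):
        data, _ = small_data
        got = match_target_drug(data.drugs)
        got_caseids = set(data.cases.loc[data.cases["primaryid"].isin(got), "caseid"])
        assert got_caseids == set(small_dataset.ground_truth.target_caseids)


@pytest.mark.parametrize(
    "value, code, years",
    [
        (6.4, "DEC", 64.0),
        (18, "MON", 1.5),
        (730.5, "DY", 2.0),
        (52.143, "WK", 1.0),
        (50, "YR", 50.0),
    ],
)
def test_normalize_age(value, code, years):
    assert normalize_age(value, code) == pytest.approx(years)


def test_normalize_age_unknowns():
    assert math.isnan(normalize_age(5, "UNK"))
    assert math.isnan(normalize_age(-3, "YR"))


def test_contingency_hand_enumeration():
    """Three cases: case1 (target) has PT X, case2 (target) has Y, case3 has X."""
    events = pd.DataFrame({"primaryid": [1, 2, 3], "pt": ["X", "Y", "X"]})
    cohort = Cohort(frozenset({1, 2}), 2, 2, 3, 3)
    t = build_contingency("X", "PT", cohort, events)
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 0)


def test_contingency_absent_term_is_zero_table():
    events = pd.DataFrame({"primaryid": [1, 2], "pt": ["X", "Y"]})
    cohort = Cohort(frozenset({1}), 1, 1, 2, 2)
    t = build_contingency("NOPE", "PT", cohort, events)
    assert (t.a, t.b) == (0, cohort.n_target_events)


def test_contingency_all_agrees_with_per_term(small_analysis):
    cohort, events = small_analysis.cohort, small_analysis.events
    cont = contingency_all(cohort, events)
    for term in list(cont.index)[:10]:
        t = build_contingency(term, "PT", cohort, events)
        row = cont.loc[term]
        assert (t.a, t.b, t.c, t.d) == (row["a"], row["b"], row["c"], row["d"])


def test_contingency_conservation(small_analysis):
    """Sum of a over PTs = target events; a+c = term's universe count."""
    cohort, events = small_analysis.cohort, small_analysis.events
    cont = contingency_all(cohort, events)
    assert cont["a"].sum() == cohort.n_target_events
    term_totals = events.groupby("pt").size()
    assert ((cont["a"] + cont["c"]) == term_totals.reindex(cont.index)).all()
    assert ((cont[["a", "b", "c", "d"]].sum(axis=1)) == cohort.n_universe_events).all()


def test_injected_pt_count_near_expected(small_config, small_analysis):
    """Injected-PT target count within 3 SD of its analytic expectation."""
    baselines = {pt: p for pt, _, p in small_config.pt_catalog}
    cont = contingency_all(small_analysis.cohort, small_analysis.events)
    n_target = small_analysis.cohort.n_target_patients
    for pt, lam in small_config.injected_signals:
        p = min(1.0, baselines[pt] * lam)
        mean, sd = n_target * p, math.sqrt(n_target * p * (1 - p))
        assert abs(cont.loc[pt, "a"] - mean) <= 3 * sd


def test_summarize_cohort_percentages(small_analysis, small_data):
    data, _ = small_data
    kept = small_analysis.dedup.kept
    summary = summarize_cohort(small_analysis.cohort, kept)
    for factor in ("sex", "age_band", "serious"):
        assert summary[factor]["percent"].sum() == pytest.approx(100.0, abs=0.05)
    epp = summary["events_per_patient"]
    assert epp.loc[0, "mean_events_per_patient"] == pytest.approx(
        round(small_analysis.cohort.n_target_events / small_analysis.cohort.n_target_patients, 1)
    )


def test_summarize_cohort_single_patient():
    cases = pd.DataFrame(
        {
            "primaryid": [1],
            "sex": ["F"],
            "age_value": [50.0],
            "age_code": ["YR"],
            "reporter": ["physician"],
            "serious": [True],
            "outcomes": [("HO",)],
        }
    )
    cohort = Cohort(frozenset({1}), 1, 1, 1, 1)
    s = summarize_cohort(cohort, cases)
    assert s["sex"].loc["F", "percent"] == 100.0
    assert s["events_per_patient"].loc[0, "mean_events_per_patient"] == 1.0


def test_summarize_zero_patients_raises():
    with pytest.raises(ValueError):
        summarize_cohort(Cohort(frozenset(), 0, 0, 0, 0), pd.DataFrame())


class TestConcomitants:
    def test_distinct_report_counting(self):
        drugs = _drugs(
            [
                (1, 1, "SORAFENIB", "", "PS"),
                (1, 2, "FUROSEMIDE", "", "C"),
                (1, 3, "FUROSEMIDE", "", "C"),  # repeat within one report
                (2, 1, "SORAFENIB", "", "PS"),
                (2, 2, "FUROSEMIDE", "", "C"),
            ]
        )
        out = count_concomitants(drugs, {1, 2}, {"SORAFENIB"})
        assert out.loc[0, "base_name"] == "FUROSEMIDE"
        assert out.loc[0, "reports"] == 2

    def test_target_drug_excluded_and_ties_alphabetical(self):
        drugs = _drugs(
            [
                (1, 1, "SORAFENIB", "", "PS"),
                (1, 2, "ZINC", "", "C"),
                (1, 3, "AMLODIPINE", "", "C"),
            ]
        )
        out = count_concomitants(drugs, {1}, {"SORAFENIB"})
        assert list(out["base_name"]) == ["AMLODIPINE", "ZINC"]

    def test_synthetic_matches_manifest(self, small_dataset, small_data):
        """With deletions excluded, counts equal the generator's bookkeeping."""
        data, _ = small_data
        gt = small_dataset.ground_truth
        from pvsignal.dedup import deduplicate

        kept = deduplicate(data.cases).kept  # no deletions: full manifest comparison
        target_pids = set(
            kept.loc[kept["caseid"].isin(gt.target_caseids), "primaryid"]
        )
        out = count_concomitants(data.drugs, target_pids).set_index("base_name")
        for name, count in gt.concomitant_counts.items():
            got = int(out["reports"].get(name, 0))
            assert got == count
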