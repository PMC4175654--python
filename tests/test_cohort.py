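"""Cohort rules against hand-enumerated oracles: transfer chaining, planned
classification, inclusion/exclusion, outcome boundaries, covariate assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rsrates import (
    ClaimsDataset, CodeLists, CohortConfig, build_covariates,
    build_mortality_cohort, build_readmission_cohort, chain_transfers,
    classify_planned,
)

ADM_COLS = [
    "patient_id", "hospital_id", "admission_date", "discharge_date",
    "principal_condition", "secondary_conditions", "procedure_codes",
    "discharge_disposition", "setting", "age_at_admission", "sex",
]
ENR_COLS = ["patient_id", "coverage_start", "coverage_end", "death_date",
            "hospice_spans"]


def adm(pid, hid, a, d, cond="AMI", sec="", proc="P_OTH", dispo="alive",
        setting="acute", age=75.0, sex="F"):
    return dict(zip(ADM_COLS, (pid, hid, a, d, cond, sec, proc, dispo,
                               setting, age, sex)))


def enr(pid, start=-2000, end=5000, death=np.nan, hospice=""):
    return dict(zip(ENR_COLS, (pid, start, end, death, hospice)))


def claims(admissions, enrollment):
    return ClaimsDataset(
        admissions=pd.DataFrame(admissions),
        enrollment=pd.DataFrame(enrollment),
        truth=pd.DataFrame(columns=["hospital_id", "true_alpha"]),
    )


# ---------------------------------------------------------------- chaining

def test_same_day_transfer_merges():
    eps = chain_transfers(pd.DataFrame([
        adm("P1", "A", 5, 10, dispo="transfer_out"),
        adm("P1", "B", 10, 14),
    ]))
    assert len(eps) == 1
    e = eps.iloc[0]
    assert (e.first_hospital, e.last_hospital) == ("A", "B")
    assert (e.admission_date, e.discharge_date) == (5, 14)


def test_two_day_gap_stays_separate():
    eps = chain_transfers(pd.DataFrame([
        adm("P1", "A", 5, 10), adm("P1", "B", 12, 14),
    ]))
    assert len(eps) == 2


def test_three_stay_chain_matches_interval_merge_oracle():
    stays = [("A", 0, 4), ("B", 5, 9), ("C", 9, 15)]
    eps = chain_transfers(pd.DataFrame(
        [adm("P1", h, a, d) for h, a, d in stays]
    ))
    # oracle: brute-force interval merging with a 1-day bridge
    merged = []
    for h, a, d in stays:
        if merged and a - merged[-1][1] <= 1:
            merged[-1] = (merged[-1][0], d)
        else:
            merged.append((a, d))
    assert len(eps) == len(merged) == 1
    assert eps.iloc[0].admission_date == 0
    assert eps.iloc[0].discharge_date == 15
    assert eps.iloc[0].first_hospital == "A"
    assert eps.iloc[0].last_hospital == "C"
    assert eps.iloc[0].n_stays == 3


def test_overlapping_stays_drop_later_record(caplog):
    eps = chain_transfers(pd.DataFrame([
        adm("P1", "A", 0, 10), adm("P1", "B", 4, 6),
    ]))
    assert len(eps) == 1
    assert eps.iloc[0].first_hospital == "A"
    assert eps.iloc[0].discharge_date == 10


def test_chain_unions_secondary_codes():
    eps = chain_transfers(pd.DataFrame([
        adm("P1", "A", 0, 2, sec="C01;C02"),
        adm("P1", "B", 3, 5, sec="C02;C03"),
    ]))
    assert eps.iloc[0].secondary_conditions == "C01;C02;C03"


# ------------------------------------------------------- planned classifier

def test_planned_truth_table():
    """Exhaustive 2x2x2 enumeration over list memberships."""
    lists = CodeLists(
        always_planned=frozenset({"AP"}),
        potentially_planned=frozenset({"PP"}),
        acute_principal=frozenset({"AMI"}),
    )
    for in_always, in_maybe, acute in itertools.product((0, 1), repeat=3):
        procs = []
        if in_always:
            procs.append("AP")
        if in_maybe:
            procs.append("PP")
        row = {"procedure_codes": ";".join(procs),
               "principal_condition": "AMI" if acute else "OTHER"}
        expected = "planned" if (in_always or (in_maybe and not acute)) \
            else "unplanned"
        assert classify_planned(row, lists) == expected


def test_missing_code_lists_raise():
    from rsrates.simulate import ConfigError
    with pytest.raises(ConfigError):
        classify_planned({"procedure_codes": "", "principal_condition": "AMI"},
                         None)


# -------------------------------------------------------- mortality cohort

def _mortality_fixture():
    """Six hand-written patients, each exercising one rule."""
    admissions = [
        adm("P1", "A", 400, 405),                          # kept, survives
        adm("P2", "A", 400, 405, age=64.0),                # under age
        adm("P3", "A", 400, 405),                          # short enrollment
        adm("P4", "A", 400, 405),                          # hospice in lookback
        adm("P5", "A", 400, 405),                          # death day 30 -> 1
        adm("P6", "A", 400, 405),                          # death day 70 -> 0
        adm("P6", "A", 420, 425),                          # same-year duplicate
    ]
    enrollment = [
        enr("P1"), enr("P2"),
        enr("P3", start=400 - 100),                        # only 100 days
        enr("P4", hospice="300:320"),
        enr("P5", death=430.0),                            # 400 + 30
        enr("P6", death=470.0),                            # past both windows
    ]
    return claims(admissions, enrollment)


def test_mortality_rules_match_hand_enumeration():
    cohort = build_mortality_cohort(_mortality_fixture(), CohortConfig(seed=0))
    t = cohort.table
    assert set(t.patient_id) == {"P1", "P5", "P6"}
    by = t.set_index("patient_id")
    assert by.loc["P5", "outcome"] == 1          # day 30 inclusive
    # P6: whichever same-year stay was drawn, death is > 30 days from both
    assert by.loc["P6", "outcome"] == 0
    assert (t.groupby(["patient_id", "period"]).size() == 1).all()
    excl = cohort.exclusions.set_index("rule")["count"]
    assert excl["under_age"] == 1
    assert excl["insufficient_enrollment"] == 1
    assert excl["hospice"] == 1
    assert excl["one_per_year_draw"] == 1
    assert excl.sum() == 7  # candidates conserved


def test_mortality_attributed_to_admitting_hospital():
    data = claims(
        [adm("P1", "A", 100, 104, dispo="transfer_out"),
         adm("P1", "B", 105, 110, cond="OTHER")],
        [enr("P1", death=120.0)],
    )
    t = build_mortality_cohort(data, CohortConfig(seed=0)).table
    assert list(t.hospital_id) == ["A"]
    assert t.iloc[0].outcome == 1                # death day 20 from admission


def test_one_per_year_draw_deterministic():
    data = _mortality_fixture()
    a = build_mortality_cohort(data, CohortConfig(seed=5)).table
    b = build_mortality_cohort(data, CohortConfig(seed=5)).table
    pd.testing.assert_frame_equal(a, b)


# ------------------------------------------------------ readmission cohort

def test_readmission_outcome_and_index_spacing():
    data = claims(
        [adm("P1", "A", 100, 103),
         adm("P1", "B", 123, 125, cond="AMI")],   # day 20 after discharge
        [enr("P1")],
    )
    cohort = build_readmission_cohort(
        data, CohortConfig(seed=0, outcome="readmission")
    )
    t = cohort.table
    # day-123 stay is an outcome event, not a second index
    assert len(t) == 1
    assert t.iloc[0].outcome == 1
    assert cohort.exclusions.set_index("rule")["count"][
        "within_30d_of_prior_index"] == 1


def test_planned_readmission_not_an_outcome():
    data = claims(
        [adm("P1", "A", 100, 103),
         adm("P1", "B", 120, 122, cond="OTHER", proc="P_ALWAYS")],
        [enr("P1")],
    )
    t = build_readmission_cohort(
        data, CohortConfig(seed=0, outcome="readmission")
    ).table
    assert t.iloc[0].outcome == 0


def test_readmission_attributed_to_discharging_hospital():
    data = claims(
        [adm("P1", "A", 100, 103, dispo="transfer_out"),
         adm("P1", "B", 104, 108, cond="OTHER")],
        [enr("P1")],
    )
    t = build_readmission_cohort(
        data, CohortConfig(seed=0, outcome="readmission")
    ).table
    assert list(t.hospital_id) == ["B"]


def test_death_in_hospital_excluded_from_readmission():
    data = claims(
        [adm("P1", "A", 100, 104, dispo="died")],
        [enr("P1", death=104.0)],
    )
    cohort = build_readmission_cohort(
        data, CohortConfig(seed=0, outcome="readmission")
    )
    assert len(cohort.table) == 0
    assert cohort.exclusions.set_index("rule")["count"]["died_in_hospital"] == 1


def test_readmission_timeline_matches_bruteforce_oracle():
    """4-admission patient timeline: compare index set and outcomes against
    an exhaustive scan over all date pairs."""
    stays = [(100, 103), (110, 112), (160, 163), (250, 252)]
    data = claims(
        [adm("P1", f"H{i}", a, d) for i, (a, d) in enumerate(stays)],
        [enr("P1")],
    )
    cohort = build_readmission_cohort(
        data, CohortConfig(seed=0, outcome="readmission")
    ).table

    # oracle: chronological scan with explicit date-pair enumeration
    indexes, outcomes = [], []
    last_dis = None
    for a, d in stays:
        if last_dis is not None and a - last_dis <= 30:
            continue
        indexes.append((a, d))
        last_dis = d
        hit = any(
            d + 1 <= a2 <= d + 30 for a2, _ in stays if a2 != a
        )
        outcomes.append(int(hit))
    assert len(cohort) == len(indexes)
    assert list(cohort.admission_date) == [a for a, _ in indexes]
    assert list(cohort.outcome) == outcomes


def test_readmission_30day_boundary():
    for gap, expected in ((30, 1), (31, 0)):
        data = claims(
            [adm("P1", "A", 100, 103),
             adm("P1", "B", 103 + gap, 105 + gap, cond="OTHER")],
            [enr("P1")],
        )
        t = build_readmission_cohort(
            data, CohortConfig(seed=0, outcome="readmission")
        ).table
        assert t.iloc[0].outcome == expected, gap


def test_observation_stay_not_an_outcome():
    data = claims(
        [adm("P1", "A", 100, 103),
         adm("P1", "B", 110, 111, cond="OTHER", setting="observation")],
        [enr("P1")],
    )
    t = build_readmission_cohort(
        data, CohortConfig(seed=0, outcome="readmission")
    ).table
    assert t.iloc[0].outcome == 0


# ------------------------------------------------------------- covariates

def test_complication_rule():
    cfg = CohortConfig(comorbidity_codes=("C01", "C02"),
                       complication_codes=("C01",))
    episodes = pd.DataFrame([
        # complication-listed code at index only -> 0
        {"patient_id": "P1", "admission_date": 400, "age_at_admission": 80.0,
         "sex": "F", "secondary_conditions": "C01"},
        # same code also 100 days prior -> 1
        {"patient_id": "P2", "admission_date": 400, "age_at_admission": 80.0,
         "sex": "M", "secondary_conditions": "C01"},
        # non-complication code at index only -> 1
        {"patient_id": "P3", "admission_date": 400, "age_at_admission": 80.0,
         "sex": "F", "secondary_conditions": "C02"},
    ])
    history = pd.DataFrame([
        adm("P2", "Z", 300, 302, cond="OTHER", sec="C01"),
    ])
    X = build_covariates(episodes, history, cfg)
    assert list(X["C01"]) == [0, 1, 0]
    assert list(X["C02"]) == [0, 0, 1]
    assert list(X["sex"]) == [0, 1, 0]


def test_simulated_cohort_invariants(small_claims, small_cohort):
    t = small_cohort.table
    # one index per patient-year
    assert (t.groupby(["patient_id", "period"]).size() == 1).all()
    # covariates complete
    assert not t[small_cohort.covariate_columns].isna().any().any()
    # waterfall conserves candidates
    excl = small_cohort.exclusions
    assert excl["count"].sum() == excl.set_index("rule")["count"].sum()
    # every retained index re-satisfies the inclusion predicates
    enr = small_claims.enrollment.set_index("patient_id")
    assert (t.age >= 65).all()
    starts = t.patient_id.map(enr.coverage_start)
    assert (starts <= t.admission_date - 365).all()


def test_readmission_index_spacing_invariant():
    cfg = CohortConfig(seed=3, outcome="readmission")
    from rsrates import SimConfig, generate_population
    data = generate_population(SimConfig(
        seed=3, outcome="readmission", n_hospitals=20,
        hospital_volume_distribution={"kind": "fixed", "n": 60},
    ))
    t = build_readmission_cohort(data, cfg).table
    t = t.sort_values(["patient_id", "admission_date"])
    prev_same = t.patient_id == t.patient_id.shift()
    gap = t.admission_date - t.discharge_date.shift()
    assert (gap[prev_same] > 30).all()
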