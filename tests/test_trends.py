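"""Trend-analysis contracts: GEE equivalences, change tabulation, and the
annual-rate panel's response to an injected quality shift."""

import numpy as np
import pandas as pd
import pytest

from rsrates import (
    CohortConfig, SimConfig, annual_rates, change_categories, gee_trend,
    generate_population,
)


def _panel(rates_by_hospital):
    rows = []
    for h, rates in rates_by_hospital.items():
        for per, r in enumerate(rates, start=1):
            if r is not None:
                rows.append((h, per, float(r), 50))
    return pd.DataFrame(rows, columns=["hospital_id", "period", "rate_pct",
                                       "n_cases"])


def test_constant_panel_gives_zero_contrasts():
    panel = _panel({f"H{i}": [12.0 + i, 12.0 + i, 12.0 + i] for i in range(8)})
    res = gee_trend(panel)
    for per, c in res.gee_coefficients.items():
        assert abs(c["estimate"]) < 1e-10
    for pair, c in res.pairwise.items():
        assert abs(c["estimate"]) < 1e-10


def test_balanced_panel_equals_ols_oracle():
    rng = np.random.default_rng(5)
    panel = _panel({
        f"H{i}": rng.normal(15, 2, 3) for i in range(20)
    })
    res = gee_trend(panel)
    # closed-form OLS on a balanced complete panel: contrasts are
    # differences of per-period means
    means = panel.groupby("period").rate_pct.mean()
    for per, c in res.gee_coefficients.items():
        assert np.isclose(c["estimate"], means[per] - means[1], atol=1e-8)
    for (a, b), c in res.pairwise.items():
        assert np.isclose(c["estimate"], means[b] - means[a], atol=1e-8)


def test_gee_invariant_to_relabeling_and_order():
    rng = np.random.default_rng(6)
    panel = _panel({f"H{i}": rng.normal(15, 2, 3) for i in range(12)})
    res1 = gee_trend(panel)
    shuffled = panel.sample(frac=1.0, random_state=1)
    shuffled["hospital_id"] = shuffled["hospital_id"].map(
        lambda h: f"X{h}"
    )
    res2 = gee_trend(shuffled)
    assert np.isclose(res1.overall_p, res2.overall_p, atol=1e-8)
    for k in res1.pairwise:
        assert np.isclose(res1.pairwise[k]["estimate"],
                          res2.pairwise[k]["estimate"], atol=1e-8)


def test_single_period_panel_rejected():
    panel = _panel({"H1": [12.0], "H2": [13.0]})
    with pytest.raises(ValueError):
        gee_trend(panel)


def test_all_single_period_hospitals_rejected():
    panel = _panel({"H1": [12.0, None], "H2": [None, 13.0]})
    with pytest.raises(ValueError):
        gee_trend(panel)


def test_unbalanced_clusters_allowed():
    rng = np.random.default_rng(7)
    d = {f"H{i}": rng.normal(15, 2, 3) for i in range(10)}
    d["H10"] = [14.0, None, None]       # single-period hospital retained
    res = gee_trend(_panel(d))
    assert res.n_hospitals == 11


def test_injected_year3_shift_lowers_year3_rates():
    """Splice a -1 logit year-3 shift into an otherwise identical dataset:
    patients whose index stay falls in year 3 come from the shifted run."""
    base_kwargs = dict(
        seed=23, n_hospitals=40,
        hospital_volume_distribution={"kind": "fixed", "n": 120},
        p_transfer=0.0,
    )
    a = generate_population(SimConfig(**base_kwargs))
    b = generate_population(SimConfig(**base_kwargs, mu=SimConfig().mu - 1.0))

    first_adm = a.admissions[a.admissions.principal_condition == "AMI"] \
        .groupby("patient_id").admission_date.min()
    year3 = set(first_adm[first_adm >= 730].index)

    adm = pd.concat([
        a.admissions[~a.admissions.patient_id.isin(year3)],
        b.admissions[b.admissions.patient_id.isin(year3)],
    ])
    enr = pd.concat([
        a.enrollment[~a.enrollment.patient_id.isin(year3)],
        b.enrollment[b.enrollment.patient_id.isin(year3)],
    ])
    spliced = type(a)(admissions=adm, enrollment=enr, truth=a.truth)

    panel = annual_rates(spliced, CohortConfig(seed=23))
    med = panel.groupby("period").rate_pct.median()
    assert med[3] < med[1]
    assert med[3] < med[2]
    res = gee_trend(panel)
    assert res.pairwise[(1, 3)]["estimate"] < 0


@pytest.mark.parametrize("seed", [29, 31])
def test_stationary_generator_periods_similar(seed):
    """Median annual rates track the (binomially noisy) yearly national
    rate; at ~2,400 cases/year its SD is ~0.7pp, so a 4pp range bound
    leaves only sampling wiggle."""
    data = generate_population(SimConfig(
        seed=seed, n_hospitals=40,
        hospital_volume_distribution={"kind": "fixed", "n": 180},
    ))
    panel = annual_rates(data, CohortConfig(seed=seed))
    med = panel.groupby("period").rate_pct.median()
    assert med.max() - med.min() < 4.0


def test_change_categories_definitions():
    prior = pd.DataFrame({
        "hospital_id": ["A", "B", "C", "D"],
        "category": ["worse", "better", "no_different", "better"],
        "n_cases": [100, 100, 100, 100],
    })
    current = pd.DataFrame({
        "hospital_id": ["A", "B", "C", "D"],
        "category": ["no_different", "better", "worse", "no_different"],
        "n_cases": [100, 100, 100, 100],
    })
    tab = change_categories(prior, current)
    assert tab.counts[("worse", "no_different")] == 1    # improved
    assert tab.counts[("better", "better")] == 1         # no change
    assert tab.counts[("no_different", "worse")] == 1    # worsened
    assert tab.n_improved == 1 and tab.n_worsened == 2
    assert tab.n_evaluated == 4
    t = tab.table()
    assert set(t.change) == {"improved", "no_change", "worsened"}
    assert t.n.sum() == 4


def test_change_categories_match_crosstab_oracle():
    rng = np.random.default_rng(11)
    cats = np.array(["better", "no_different", "worse"])
    n = 1000
    prior = pd.DataFrame({
        "hospital_id": [f"H{i}" for i in range(n)],
        "category": rng.choice(cats, n),
        "n_cases": rng.integers(25, 500, n),
    })
    current = prior.copy()
    current["category"] = rng.choice(cats, n)
    tab = change_categories(prior, current)
    oracle = pd.crosstab(prior.category, current.category)
    for (a, b), cnt in tab.counts.items():
        assert cnt == oracle.loc[a, b]
    assert sum(tab.counts.values()) == n


def test_change_categories_excludes_small_and_unmatched():
    prior = pd.DataFrame({
        "hospital_id": ["A", "B", "C"],
        "category": ["worse", "better", "no_different"],
        "n_cases": [100, 10, 100],            # B below threshold
    })
    current = pd.DataFrame({
        "hospital_id": ["A", "D"],
        "category": ["no_different", "worse"],
        "n_cases": [100, 100],
    })
    tab = change_categories(prior, current)
    assert tab.n_evaluated == 1
    assert tab.n_excluded == 3                # B, C, D
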