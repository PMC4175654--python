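"""Annual rate panels, GEE trend tests, and performance-category changes.

Annual risk-standardized rates are computed by rebuilding the cohort and
refitting the risk model independently within each measure year (July-June,
365-day blocks of the measurement window).  The trend test is a marginal
(GEE) model of annual hospital rates on period indicators with an
exchangeable working correlation and robust (sandwich) standard errors;
pairwise period contrasts are Wald tests on the same fit.  Raw p-values are
reported without multiplicity adjustment.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortConfig, build_cohort
from .model import RandomInterceptLogit
from .simulate import ClaimsDataset
from .standardize import hospital_rates, national_crude_rate


def annual_rates(
    data: ClaimsDataset,
    config: CohortConfig,
    method: str = "laplace",
    n_quad: int = 9,
) -> pd.DataFrame:
    """Per-hospital, per-measure-year risk-standardized rates.

    Each year's cohort is built independently (the one-per-year and spacing
    rules see only that year's window) and the model is refit per year.
    Hospital-years with zero cases are simply absent.  Returns columns
    hospital_id, period, rate_pct, n_cases.
    """
    start, end = config.window
    n_periods = max(1, int(np.ceil((end - start) / config.period_days)))
    panels = []
    for k in range(n_periods):
        win = (start + k * config.period_days,
               min(end, start + (k + 1) * config.period_days))
        cfg_k = replace(config, window=win)
        cohort = build_cohort(data, cfg_k)
        if len(cohort.table) == 0:
            continue
        est = RandomInterceptLogit(method=method, n_quad=n_quad)
        est.fit(
            cohort.table[cohort.covariate_columns],
            cohort.table["outcome"],
            cohort.table["hospital_id"],
        )
        rates = hospital_rates(
            est, cohort.table, cohort.covariate_columns,
            national_crude_rate(cohort.table),
        )
        rates["period"] = k + 1
        panels.append(rates[["hospital_id", "period", "rate_pct", "n_cases"]])
    if not panels:
        return pd.DataFrame(
            columns=["hospital_id", "period", "rate_pct", "n_cases"]
        )
    return pd.concat(panels, ignore_index=True)


@dataclass
class TrendResult:
    period_means: dict[int, float]
    period_medians: dict[int, float]
    period_iqrs: dict[int, tuple[float, float]]
    gee_coefficients: dict[int, dict[str, float]]   # period -> est/se/p vs first
    pairwise: dict[tuple[int, int], dict[str, float]]
    overall_p: float                                 # Wald: any period effect
    n_hospitals: int

    def to_json(self, path) -> None:
        payload = {
            "period_means": {str(k): v for k, v in self.period_means.items()},
            "period_medians": {str(k): v for k, v in self.period_medians.items()},
            "period_iqrs": {str(k): list(v) for k, v in self.period_iqrs.items()},
            "gee_coefficients": {
                str(k): v for k, v in self.gee_coefficients.items()
            },
            "pairwise": {f"{a}-{b}": v for (a, b), v in self.pairwise.items()},
            "overall_p": self.overall_p,
            "n_hospitals": self.n_hospitals,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def gee_trend(panel: pd.DataFrame) -> TrendResult:
    """Test whether mean annual rates changed across periods.

    Identity-link Gaussian GEE with categorical period indicators,
    exchangeable working correlation, robust standard errors, clusters =
    hospitals (unbalanced panels allowed).  Pairwise contrasts are Wald
    tests of period-mean differences.
    """
    periods = sorted(panel["period"].unique())
    if len(periods) < 2:
        raise ValueError("gee_trend needs at least two periods")
    sizes = panel.groupby("hospital_id")["period"].nunique()
    if (sizes >= 2).sum() < 2:
        raise ValueError(
            "gee_trend needs >= 2 hospitals observed in >= 2 periods"
        )

    panel = panel.sort_values(["hospital_id", "period"], kind="mergesort")
    dummies = pd.get_dummies(
        pd.Categorical(panel["period"], categories=periods), drop_first=True,
        dtype=float,
    )
    exog = sm.add_constant(dummies.to_numpy())
    endog = panel["rate_pct"].to_numpy(float)
    grp = panel["hospital_id"].to_numpy()
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sm.GEE(
                endog, exog, groups=grp, family=sm.families.Gaussian(),
                cov_struct=sm.cov_struct.Exchangeable(),
            ).fit()
        degenerate = not np.all(np.isfinite(res.params))
    except (ValueError, np.linalg.LinAlgError):
        res, degenerate = None, True
    if degenerate:
        # degenerate working correlation (e.g. constant-within-hospital
        # panel drives the exchangeable rho to 1); refit under independence,
        # still with robust standard errors
        try:
            res = sm.GEE(
                endog, exog, groups=grp, family=sm.families.Gaussian(),
                cov_struct=sm.cov_struct.Independence(),
            ).fit()
        except (ValueError, np.linalg.LinAlgError):
            res = None
    if res is not None:
        params = res.params
        cov = res.cov_params()
    else:
        # zero residual variance: point estimates by least squares, no
        # sampling uncertainty left to report
        params, *_ = np.linalg.lstsq(exog, endog, rcond=None)
        cov = np.zeros((exog.shape[1], exog.shape[1]))
    if not np.all(np.isfinite(cov)):
        cov = np.zeros_like(cov)

    coef = {}
    for j, per in enumerate(periods[1:], start=1):
        est, se = params[j], float(np.sqrt(cov[j, j]))
        z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
        from scipy.stats import norm
        coef[per] = {
            "estimate": float(est), "se": se,
            "p": float(2 * norm.sf(abs(z))) if se > 0 else (0.0 if est else 1.0),
        }

    from scipy.stats import norm
    pairwise = {}
    # contrast vector per period: mean_k = const + coef_k (coef_base = 0)
    vecs = {periods[0]: np.zeros(len(periods))}
    for j, per in enumerate(periods[1:], start=1):
        v = np.zeros(len(periods))
        v[j] = 1.0
        vecs[per] = v
    for a, b in itertools.combinations(periods, 2):
        c = vecs[b] - vecs[a]
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        if se > 0:
            p = float(2 * norm.sf(abs(est / se)))
        else:
            p = 0.0 if abs(est) > 0 else 1.0
        pairwise[(a, b)] = {"estimate": est, "se": se, "p": p}

    # joint Wald test that all period coefficients are zero (chi-square)
    from scipy.stats import chi2
    k = len(periods) - 1
    b = params[1:]
    V = cov[1:, 1:]
    try:
        stat = float(b @ np.linalg.solve(V, b))
        overall_p = float(chi2.sf(stat, k))
    except np.linalg.LinAlgError:
        overall_p = float("nan")

    grouped = panel.groupby("period")["rate_pct"]
    return TrendResult(
        period_means={int(k): float(v) for k, v in grouped.mean().items()},
        period_medians={int(k): float(v) for k, v in grouped.median().items()},
        period_iqrs={
            int(k): (float(g.quantile(0.25)), float(g.quantile(0.75)))
            for k, g in grouped
        },
        gee_coefficients=coef,
        pairwise=pairwise,
        overall_p=overall_p,
        n_hospitals=int(panel["hospital_id"].nunique()),
    )


#: Table-3-style transition labels
IMPROVED = (("worse", "no_different"), ("no_different", "better"),
            ("worse", "better"))
WORSENED = (("no_different", "worse"), ("better", "no_different"),
            ("better", "worse"))
NO_CHANGE = (("worse", "worse"), ("no_different", "no_different"),
             ("better", "better"))


@dataclass
class ChangeTabulation:
    counts: dict[tuple[str, str], int]
    n_evaluated: int
    n_excluded: int

    def table(self) -> pd.DataFrame:
        rows = []
        for group, pairs in (("improved", IMPROVED), ("no_change", NO_CHANGE),
                             ("worsened", WORSENED)):
            for prior, current in pairs:
                rows.append((group, f"{prior} -> {current}",
                             self.counts.get((prior, current), 0)))
        return pd.DataFrame(rows, columns=["change", "transition", "n"])

    @property
    def n_improved(self) -> int:
        return sum(self.counts.get(p, 0) for p in IMPROVED)

    @property
    def n_worsened(self) -> int:
        return sum(self.counts.get(p, 0) for p in WORSENED)

    @property
    def n_no_change(self) -> int:
        return sum(self.counts.get(p, 0) for p in NO_CHANGE)


def change_categories(
    prior: pd.DataFrame,
    current: pd.DataFrame,
    min_cases: int = 25,
) -> ChangeTabulation:
    """Cross-tabulate performance-category changes between two periods.

    Hospitals below the case threshold in either period, or present in only
    one, are excluded and counted separately.  Cell counts over the 3x3
    transition grid sum to the number of hospitals evaluated in both.
    """
    def prep(df):
        df = df[df["category"] != "not_reported"]
        if "n_cases" in df.columns:
            df = df[df["n_cases"] >= min_cases]
        return df.set_index("hospital_id")["category"]

    a, b = prep(prior), prep(current)
    common = a.index.intersection(b.index)
    all_ids = set(prior["hospital_id"]) | set(current["hospital_id"])
    n_excluded = len(all_ids) - len(common)
    counts: dict[tuple[str, str], int] = {}
    for h in common:
        key = (a.loc[h], b.loc[h])
        counts[key] = counts.get(key, 0) + 1
    tab = ChangeTabulation(
        counts=counts, n_evaluated=len(common), n_excluded=n_excluded
    )
    assert sum(counts.values()) == tab.n_evaluated
    return tab
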