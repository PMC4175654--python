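"""Measure-cohort construction from claims-like tables.

Implements the inclusion/exclusion, attribution and outcome-ascertainment
rules of the publicly reported 30-day mortality and unplanned-readmission
measures: transfer chaining into episodes of care, age and enrollment
eligibility, hospice exclusion, one-index-per-patient-per-year selection for
mortality, 30-day index spacing for readmission, planned-readmission
classification from procedure/diagnosis code lists, and risk-adjustment
covariate assembly with the complication-of-care rule.

Day-count conventions: the mortality outcome window is days 0..30 inclusive
from admission; the readmission window is days 1..30 inclusive after
discharge; a next acute admission within 1 day of discharge is a transfer
chain, not a readmission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .simulate import ClaimsDataset, ConfigError

logger = logging.getLogger(__name__)


@dataclass
class CodeLists:
    """Planned-readmission code lists (structure of the public algorithm;
    the production code tables are configuration, not shipped)."""

    always_planned: frozenset
    potentially_planned: frozenset
    acute_principal: frozenset

    @classmethod
    def default(cls) -> "CodeLists":
        return cls(
            always_planned=frozenset({"P_ALWAYS"}),
            potentially_planned=frozenset({"P_MAYBE"}),
            acute_principal=frozenset({"AMI", "HF", "PN"}),
        )

    @classmethod
    def from_yaml(cls, path) -> "CodeLists":
        raw = yaml.safe_load(open(path))
        try:
            return cls(
                always_planned=frozenset(raw["always_planned"]),
                potentially_planned=frozenset(raw["potentially_planned"]),
                acute_principal=frozenset(raw["acute_principal"]),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"code list file missing section: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "always_planned": sorted(self.always_planned),
                    "potentially_planned": sorted(self.potentially_planned),
                    "acute_principal": sorted(self.acute_principal),
                },
                fh,
            )


@dataclass
class CohortConfig:
    condition: str = "AMI"
    outcome: str = "mortality"
    window: tuple[int, int] = (0, 1095)
    min_age: float = 65.0
    lookback_days: int = 365
    outcome_horizon_days: int = 30
    min_cases_for_reporting: int = 25
    period_days: int = 365          # July–June measure year, in whole days
    comorbidity_codes: tuple[str, ...] = ("C01", "C02", "C03", "C04")
    complication_codes: tuple[str, ...] = ()
    code_lists: CodeLists = field(default_factory=CodeLists.default)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome_horizon_days <= 0:
            raise ConfigError("outcome_horizon_days must be positive")
        if self.lookback_days <= 0:
            raise ConfigError("lookback_days must be positive")
        if self.outcome not in ("mortality", "readmission"):
            raise ConfigError("outcome must be 'mortality' or 'readmission'")


@dataclass
class Cohort:
    """Index-admission table plus the exclusion waterfall that produced it."""

    table: pd.DataFrame
    exclusions: pd.DataFrame
    config: CohortConfig

    @property
    def covariate_columns(self) -> list[str]:
        return ["age", "sex"] + list(self.config.comorbidity_codes)


def classify_planned(admission, code_lists: CodeLists) -> str:
    """Classify one admission as 'planned' or 'unplanned'.

    Planned iff a procedure is on the always-planned list, or a procedure is
    on the potentially-planned list and the principal condition is not acute.
    ``admission`` may be a mapping/namedtuple with ``procedure_codes`` (string
    of ';'-joined codes or an iterable) and ``principal_condition``.
    """
    if code_lists is None:
        raise ConfigError("code_lists are required for planned classification")
    for name in ("always_planned", "potentially_planned", "acute_principal"):
        if getattr(code_lists, name, None) is None:
            raise ConfigError(f"code_lists missing '{name}'")
    procs = getattr(admission, "procedure_codes", None)
    if procs is None:
        procs = admission["procedure_codes"]
    if isinstance(procs, str):
        procs = set(p for p in procs.split(";") if p)
    else:
        procs = set(procs)
    principal = getattr(admission, "principal_condition", None)
    if principal is None:
        principal = admission["principal_condition"]
    if procs & code_lists.always_planned:
        return "planned"
    if procs & code_lists.potentially_planned and principal not in code_lists.acute_principal:
        return "planned"
    return "unplanned"


def chain_transfers(admissions: pd.DataFrame) -> pd.DataFrame:
    """Merge same-patient acute admissions separated by ≤ 1 day into episodes.

    Episodes retain the first hospital (mortality attribution), the last
    hospital (readmission attribution), the first admission date and last
    discharge date, the first record's principal condition, age, sex and
    procedure codes, and the union of secondary conditions.  Overlapping
    same-patient acute stays (negative gap) drop the later record with a
    logged warning.
    """
    acute = admissions[admissions["setting"] == "acute"].copy()
    acute = acute.sort_values(
        ["patient_id", "admission_date", "discharge_date"], kind="mergesort"
    ).reset_index(drop=True)

    # drop overlapping (negative-gap) stays; repeat because a dropped record's
    # discharge must not extend the episode it was dropped from
    n_dropped = 0
    while len(acute):
        prev_dis = (
            acute.groupby("patient_id", sort=False)["discharge_date"]
            .cummax()
            .groupby(acute["patient_id"], sort=False)
            .shift()
        )
        overlap = (acute["admission_date"] - prev_dis) < 0
        if not overlap.any():
            break
        n_dropped += int(overlap.sum())
        acute = acute[~overlap].reset_index(drop=True)
    if n_dropped:
        logger.warning(
            "chain_transfers dropped %d overlapping acute records", n_dropped
        )
    if len(acute) == 0:
        return pd.DataFrame(
            columns=[
                "patient_id", "first_hospital", "last_hospital",
                "admission_date", "discharge_date", "principal_condition",
                "secondary_conditions", "procedure_codes",
                "all_procedure_codes", "discharge_disposition",
                "age_at_admission", "sex", "n_stays",
            ]
        )

    prev_dis = (
        acute.groupby("patient_id", sort=False)["discharge_date"]
        .cummax()
        .groupby(acute["patient_id"], sort=False)
        .shift()
    )
    gap = acute["admission_date"] - prev_dis
    new_episode = gap.isna() | (gap > 1)
    epi = new_episode.cumsum()

    def _union(strings):
        out: set = set()
        for s in strings:
            out |= _codes(s)
        return ";".join(sorted(out))

    grouped = acute.groupby(epi, sort=False)
    out = pd.DataFrame({
        "patient_id": grouped["patient_id"].first(),
        "first_hospital": grouped["hospital_id"].first(),
        "last_hospital": grouped["hospital_id"].last(),
        "admission_date": grouped["admission_date"].first(),
        "discharge_date": grouped["discharge_date"].last(),
        "principal_condition": grouped["principal_condition"].first(),
        "secondary_conditions": grouped["secondary_conditions"].agg(_union),
        "procedure_codes": grouped["procedure_codes"].first(),
        "all_procedure_codes": grouped["procedure_codes"].agg(_union),
        "discharge_disposition": grouped["discharge_disposition"].last(),
        "age_at_admission": grouped["age_at_admission"].first(),
        "sex": grouped["sex"].first(),
        "n_stays": grouped.size(),
    })
    return out.reset_index(drop=True)


def _codes(s) -> set:
    if isinstance(s, str):
        return set(c for c in s.split(";") if c)
    return set(s) if s is not None else set()


def build_covariates(
    episodes: pd.DataFrame,
    admissions: pd.DataFrame,
    config: CohortConfig,
) -> pd.DataFrame:
    """Assemble the risk-adjustment covariate matrix for index episodes.

    Comorbidity indicators come from the index episode's secondary conditions
    and from any claim of the patient in the lookback window, except codes on
    the configured possible-complication list, which count only when present
    in a lookback claim (complications of the index stay must not credit the
    hospital's case-mix).  Age and sex are always included.  Absent history
    simply yields indicator 0.
    """
    epi = episodes.reset_index(drop=True)
    n = len(epi)
    out = {
        "age": epi["age_at_admission"].to_numpy(float),
        "sex": (epi["sex"] == "M").to_numpy(int),
    }
    comp = set(config.complication_codes)
    watched = set(config.comorbidity_codes)
    col_pos = {c: j for j, c in enumerate(config.comorbidity_codes)}

    index_flags = np.zeros((n, len(watched)), dtype=bool)
    sec = epi["secondary_conditions"].str.split(";")
    for i, codes in enumerate(sec):
        if not isinstance(codes, list):
            continue
        for c in codes:
            if c in watched:
                index_flags[i, col_pos[c]] = True

    # lookback claims: explode (patient, claim date, code) once, join to
    # episodes by patient, keep claims in [index - lookback, index - 1]
    lookback_flags = np.zeros((n, len(watched)), dtype=bool)
    if n and len(admissions):
        claims = admissions[["patient_id", "admission_date",
                             "secondary_conditions"]].copy()
        claims["code"] = claims["secondary_conditions"].str.split(";")
        claims = claims.explode("code")
        claims = claims[claims["code"].isin(watched)]
        if len(claims):
            left = epi[["patient_id", "admission_date"]].reset_index()
            merged = left.merge(
                claims[["patient_id", "admission_date", "code"]],
                on="patient_id", suffixes=("", "_claim"),
            )
            lo = merged["admission_date"] - config.lookback_days
            ok = (merged["admission_date_claim"] >= lo) & (
                merged["admission_date_claim"] <= merged["admission_date"] - 1
            )
            merged = merged[ok]
            for i, c in zip(merged["index"], merged["code"]):
                lookback_flags[i, col_pos[c]] = True

    for c in config.comorbidity_codes:
        j = col_pos[c]
        if c in comp:
            present = lookback_flags[:, j]
        else:
            present = index_flags[:, j] | lookback_flags[:, j]
        out[c] = present.astype(int)
    return pd.DataFrame(out, index=episodes.index)


def _eligibility(
    episodes: pd.DataFrame,
    enrollment: pd.DataFrame,
    config: CohortConfig,
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Apply the shared inclusion rules sequentially, returning the surviving
    episodes and the exclusion waterfall (rule, count) in application order."""
    start, end = config.window
    waterfall = []
    df = episodes

    m = (df["admission_date"] >= start) & (df["admission_date"] < end)
    waterfall.append(("outside_window", int((~m).sum())))
    df = df[m]

    m = df["age_at_admission"] >= config.min_age
    waterfall.append(("under_age", int((~m).sum())))
    df = df[m]

    enr = enrollment.set_index("patient_id")
    known = df["patient_id"].isin(enr.index)
    cov_start = df["patient_id"].map(enr["coverage_start"])
    cov_end = df["patient_id"].map(enr["coverage_end"])
    m = (
        known
        & (cov_start <= df["admission_date"] - config.lookback_days)
        & (cov_end >= df["admission_date"])
    )
    waterfall.append(("insufficient_enrollment", int((~m).sum())))
    df = df[m]

    spans = enr["hospice_spans"].to_dict()

    def in_hospice(row) -> bool:
        raw = spans.get(row.patient_id, "")
        if not isinstance(raw, str) or not raw:
            return False
        lo = row.admission_date - config.lookback_days
        for part in raw.split(";"):
            s, _, e = part.partition(":")
            if int(s) <= row.admission_date and int(e) >= lo:
                return True
        return False

    if len(df):
        m = pd.Series(
            [not in_hospice(r) for r in df.itertuples(index=False)],
            index=df.index,
        )
    else:
        m = pd.Series(dtype=bool)
    waterfall.append(("hospice", int((~m).sum())))
    df = df[m]
    return df, waterfall


def _finalize(table, waterfall, n_candidates, config) -> Cohort:
    excl = pd.DataFrame(waterfall, columns=["rule", "count"])
    excl.loc[len(excl)] = ("retained", len(table))
    assert excl["count"].sum() == n_candidates
    if table.empty:
        logger.warning("cohort is empty; exclusion waterfall: %s",
                       excl.to_dict("records"))
    return Cohort(table=table.reset_index(drop=True), exclusions=excl,
                  config=config)


def build_mortality_cohort(data: ClaimsDataset, config: CohortConfig) -> Cohort:
    """Mortality measure cohort: one randomly selected eligible hospitalization
    per patient per measure year; outcome = death from any cause within 30
    days of admission; attributed to the first (admitting) hospital."""
    episodes = chain_transfers(data.admissions)
    cand = episodes[episodes["principal_condition"] == config.condition]
    n_cand = len(cand)
    df, waterfall = _eligibility(cand, data.enrollment, config)

    start = config.window[0]
    df = df.copy()
    df["period"] = 1 + (df["admission_date"] - start) // config.period_days

    # one-per-(patient, year) seeded uniform draw; sorting first makes the
    # selection invariant to input row order
    df = df.sort_values(
        ["patient_id", "period", "admission_date", "first_hospital"],
        kind="mergesort",
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    df["_u"] = rng.random(len(df))
    keep = df.groupby(["patient_id", "period"], sort=False)["_u"].idxmin()
    dropped = len(df) - len(keep)
    waterfall.append(("one_per_year_draw", dropped))
    df = df.loc[keep].drop(columns="_u")

    enr = data.enrollment.set_index("patient_id")
    death = df["patient_id"].map(enr["death_date"]).astype(float)
    df["outcome"] = (
        death.notna()
        & (death <= df["admission_date"] + config.outcome_horizon_days)
    ).astype(int)
    df["hospital_id"] = df["first_hospital"]

    cov = build_covariates(df, data.admissions, config)
    table = pd.concat(
        [df[["patient_id", "hospital_id", "admission_date", "discharge_date",
             "period", "outcome"]], cov],
        axis=1,
    )
    return _finalize(table, waterfall, n_cand, config)


def build_readmission_cohort(data: ClaimsDataset, config: CohortConfig) -> Cohort:
    """Readmission measure cohort: index episodes discharged alive, with 30-day
    spacing between a patient's index admissions; outcome = unplanned acute
    readmission on days 1..30 after discharge; attributed to the last
    (discharging) hospital of the episode."""
    episodes = chain_transfers(data.admissions)
    episodes = episodes.sort_values(
        ["patient_id", "admission_date"], kind="mergesort"
    )
    always = config.code_lists.always_planned
    maybe = config.code_lists.potentially_planned
    acute_set = config.code_lists.acute_principal
    if always is None or maybe is None or acute_set is None:
        raise ConfigError("code_lists incomplete")
    proc_sets = [
        set(p for p in s.split(";") if p)
        for s in episodes["procedure_codes"].astype(str)
    ]
    principals = episodes["principal_condition"].to_numpy()
    episodes["planned"] = [
        "planned"
        if (ps & always) or (ps & maybe and pr not in acute_set)
        else "unplanned"
        for ps, pr in zip(proc_sets, principals)
    ]

    cand = episodes[episodes["principal_condition"] == config.condition]
    n_cand = len(cand)
    df, waterfall = _eligibility(cand, data.enrollment, config)

    m = df["discharge_disposition"] != "died"
    waterfall.append(("died_in_hospital", int((~m).sum())))
    df = df[m]

    # 30-day index spacing: scan each patient's eligible episodes in time
    # order; an episode admitted within `horizon` days after the previous
    # index's discharge cannot itself be an index
    horizon = config.outcome_horizon_days
    df = df.sort_values(["patient_id", "admission_date"], kind="mergesort")
    pids = df["patient_id"].to_numpy()
    adms = df["admission_date"].to_numpy()
    diss = df["discharge_date"].to_numpy()
    keep = np.zeros(len(df), dtype=bool)
    last_pid, last_index_discharge = None, None
    for i in range(len(df)):
        if pids[i] != last_pid:
            last_pid, last_index_discharge = pids[i], None
        if (
            last_index_discharge is not None
            and adms[i] - last_index_discharge <= horizon
        ):
            continue
        keep[i] = True
        last_index_discharge = diss[i]
    waterfall.append(("within_30d_of_prior_index", int((~keep).sum())))
    df = df[keep].copy()

    # outcome scan over ALL acute episodes (any condition), unplanned only;
    # episodes are patient-sorted, so searchsorted windows per patient work
    unplanned = episodes[episodes["planned"] == "unplanned"]
    by_patient: dict = {}
    u_pid = unplanned["patient_id"].to_numpy()
    u_adm = unplanned["admission_date"].to_numpy()
    bounds = np.flatnonzero(np.r_[True, u_pid[1:] != u_pid[:-1]])
    for s, e in zip(bounds, np.r_[bounds[1:], len(u_pid)] if len(bounds) else []):
        by_patient[u_pid[s]] = np.sort(u_adm[s:e])
    outcomes = np.zeros(len(df), dtype=int)
    d_pid = df["patient_id"].to_numpy()
    d_dis = df["discharge_date"].to_numpy()
    for i in range(len(df)):
        arr = by_patient.get(d_pid[i])
        if arr is None:
            continue
        lo = d_dis[i] + 1
        j = np.searchsorted(arr, lo, side="left")
        if j < len(arr) and arr[j] <= d_dis[i] + horizon:
            outcomes[i] = 1
    df["outcome"] = outcomes
    df["hospital_id"] = df["last_hospital"]
    start = config.window[0]
    df["period"] = 1 + (df["admission_date"] - start) // config.period_days

    cov = build_covariates(df, data.admissions, config)
    table = pd.concat(
        [df[["patient_id", "hospital_id", "admission_date", "discharge_date",
             "period", "outcome"]], cov],
        axis=1,
    )
    return _finalize(table, waterfall, n_cand, config)


def build_cohort(data: ClaimsDataset, config: CohortConfig) -> Cohort:
    if config.outcome == "mortality":
        return build_mortality_cohort(data, config)
    return build_readmission_cohort(data, config)
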