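"""Synthetic inpatient-claims generator with known hospital quality effects.

Emulates Medicare fee-for-service / VA-style inpatient claims for a single
condition-outcome measure: hospitals carry latent quality effects (random
intercepts on the logit scale), patients carry a case-mix of age, sex and
binary comorbidities, and the measured outcome (30-day death or 30-day
unplanned readmission) is drawn from a logistic model on that case-mix.
Around the measured process the generator emits the administrative furniture
a cohort builder must survive: transfer chains, planned readmissions,
observation stays, prior-history admissions, hospice spans, enrollment gaps
and death dates.  A ground-truth table of hospital effects is returned so
downstream estimates can be checked against what generated the data.

All dates are integer day offsets from the start of the measurement window;
a measure year is 365 days, so a 3-year window is days 0..1094.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit


class ConfigError(ValueError):
    """Invalid simulation or measure configuration; message names the field."""


CONDITIONS = ("AMI", "HF", "PN", "OTHER")
OUTCOMES = ("mortality", "readmission")

#: procedure codes the default planned-readmission code lists recognise
ALWAYS_PLANNED_PROC = "P_ALWAYS"
MAYBE_PLANNED_PROC = "P_MAYBE"
OTHER_PROC = "P_OTH"


@dataclass
class SimConfig:
    """Study conditions for one synthetic condition-outcome measure.

    Defaults emulate the AMI mortality measure at desk scale: the hospital
    volume quartiles (10 / 40 / 156 eligible cases over three years) and the
    patient age quartiles (72 / 79 / 86) follow the published national cohort
    summaries; the national intercept ``mu`` puts the crude 30-day rate near
    15%; ``tau`` is the between-hospital SD of the latent quality effect on
    the logit scale.
    """

    n_hospitals: int = 80
    hospital_volume_distribution: dict = field(
        default_factory=lambda: {
            "kind": "lognormal-quartiles", "median": 40, "q25": 10, "q75": 156,
        }
    )
    tau: float = 0.20
    mu: float = -2.25
    beta: tuple[float, ...] = (0.40, 0.30, 0.25, 0.20)
    covariate_prevalences: tuple[float, ...] = (0.30, 0.25, 0.20, 0.15)
    beta_age: float = 0.04      # log-odds per year, centred at the median age
    beta_sex: float = 0.10      # male vs female
    age_distribution: dict = field(
        default_factory=lambda: {"median": 79.0, "q25": 72.0, "q75": 86.0}
    )
    p_male: float = 0.5
    condition: str = "AMI"
    outcome: str = "mortality"
    p_planned_readmission: float = 0.10
    p_transfer: float = 0.05
    p_hospice: float = 0.02
    p_short_enrollment: float = 0.05
    p_underage: float = 0.03
    p_repeat_index: float = 0.12
    p_prior_admission: float = 0.20
    p_observation_stay: float = 0.03
    p_background_readmission: float = 0.08   # non-modelled readmits (mortality runs)
    p_background_death: float = 0.03         # non-modelled deaths (readmission runs)
    measurement_window: tuple[int, int] = (0, 1095)
    lookback_days: int = 365
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hospitals < 1:
            raise ConfigError("n_hospitals must be a positive integer")
        if self.tau < 0:
            raise ConfigError("tau must be non-negative")
        if len(self.beta) != len(self.covariate_prevalences):
            raise ConfigError(
                "beta and covariate_prevalences must have equal length"
            )
        for name in (
            "p_male", "p_planned_readmission", "p_transfer", "p_hospice",
            "p_short_enrollment", "p_underage", "p_repeat_index",
            "p_prior_admission", "p_observation_stay",
            "p_background_readmission", "p_background_death",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1]")
        for p in self.covariate_prevalences:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(
                    "covariate_prevalences entries must be in [0, 1]"
                )
        start, end = self.measurement_window
        if not start < end:
            raise ConfigError("measurement_window start must precede end")
        if self.condition not in CONDITIONS:
            raise ConfigError(f"condition must be one of {CONDITIONS}")
        if self.outcome not in OUTCOMES:
            raise ConfigError(f"outcome must be one of {OUTCOMES}")
        kind = self.hospital_volume_distribution.get("kind")
        if kind not in ("lognormal-quartiles", "fixed", "poisson"):
            raise ConfigError(
                "hospital_volume_distribution.kind must be "
                "'lognormal-quartiles', 'fixed' or 'poisson'"
            )
        if kind == "lognormal-quartiles":
            for key in ("median", "q25", "q75"):
                if key not in self.hospital_volume_distribution:
                    raise ConfigError(
                        f"hospital_volume_distribution missing '{key}'"
                    )
        if kind == "fixed" and "n" not in self.hospital_volume_distribution:
            raise ConfigError("hospital_volume_distribution missing 'n'")
        if kind == "poisson" and "mean" not in self.hospital_volume_distribution:
            raise ConfigError("hospital_volume_distribution missing 'mean'")
        for key in ("median", "q25", "q75"):
            if key not in self.age_distribution:
                raise ConfigError(f"age_distribution missing '{key}'")

    @property
    def comorbidity_codes(self) -> list[str]:
        return [f"C{k + 1:02d}" for k in range(len(self.beta))]

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list, indent=2)


@dataclass
class ClaimsDataset:
    """Admissions + enrollment tables with the generating hospital effects."""

    admissions: pd.DataFrame
    enrollment: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig | None = None

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.admissions.to_csv(outdir / "admissions.csv", index=False)
        self.enrollment.to_csv(outdir / "enrollment.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        if self.config is not None:
            (outdir / "sim_config.json").write_text(self.config.to_json())

    @classmethod
    def from_csv(cls, indir) -> "ClaimsDataset":
        from pathlib import Path

        indir = Path(indir)
        adm = pd.read_csv(
            indir / "admissions.csv",
            keep_default_na=False,
            dtype={"secondary_conditions": str, "procedure_codes": str},
        )
        enr = pd.read_csv(
            indir / "enrollment.csv",
            keep_default_na=False,
            dtype={"hospice_spans": str},
        )
        enr["death_date"] = pd.to_numeric(
            enr["death_date"].replace("", np.nan)
        ).astype("Float64")
        truth_path = indir / "truth.csv"
        truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame(
            columns=["hospital_id", "true_alpha", "n_index_stays"]
        )
        return cls(admissions=adm, enrollment=enr, truth=truth)


def _substream(seed: int, channel: int) -> np.random.Generator:
    """Named substream of the global seed (documented hierarchy, channels 0..9)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), channel]))


def _draw_volumes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    spec = cfg.hospital_volume_distribution
    kind = spec["kind"]
    if kind == "fixed":
        return np.full(cfg.n_hospitals, int(spec["n"]))
    if kind == "poisson":
        return np.maximum(1, rng.poisson(float(spec["mean"]), cfg.n_hospitals))
    # lognormal matched to the given quartiles
    med, q25, q75 = (float(spec[k]) for k in ("median", "q25", "q75"))
    if not 0 < q25 <= med <= q75:
        raise ConfigError("hospital_volume_distribution quartiles must be ordered")
    sigma = (np.log(q75) - np.log(q25)) / (2 * 0.674489750196082)
    vols = rng.lognormal(np.log(med), sigma, cfg.n_hospitals)
    return np.clip(np.round(vols), 1, 5000).astype(int)


def _draw_ages(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Truncated-normal ages ≥ 65 matched to the configured quartiles, plus a
    small under-65 fraction so the age exclusion rule has work to do."""
    med = float(cfg.age_distribution["median"])
    iqr = float(cfg.age_distribution["q75"]) - float(cfg.age_distribution["q25"])
    sd = iqr / 1.348979500392164
    ages = rng.normal(med, sd, n)
    while True:
        bad = (ages < 65) | (ages > 105)
        if not bad.any():
            break
        ages[bad] = rng.normal(med, sd, bad.sum())
    under = rng.random(n) < cfg.p_underage
    ages[under] = rng.uniform(55, 64.99, under.sum())
    return np.round(ages, 1)


def generate_population(config: SimConfig) -> ClaimsDataset:
    """Generate a seeded synthetic claims dataset for one measure.

    The measured outcome of each index-eligible stay is Bernoulli with
    probability ``expit(mu + alpha_h + x·beta)`` where ``alpha_h ~ N(0, tau²)``
    is the attributed hospital's latent effect.  Identical configs (including
    seed) produce byte-identical tables.
    """
    cfg = config
    rng_h = _substream(cfg.seed, 0)       # hospitals
    rng_p = _substream(cfg.seed, 1)       # patients / case-mix
    rng_y = _substream(cfg.seed, 2)       # outcomes
    rng_f = _substream(cfg.seed, 3)       # furniture (transfers, hospice, ...)

    win_start, win_end = cfg.measurement_window
    win_len = win_end - win_start

    hospital_ids = np.array([f"H{i + 1:03d}" for i in range(cfg.n_hospitals)])
    alphas = rng_h.normal(0.0, cfg.tau, cfg.n_hospitals)
    volumes = _draw_volumes(cfg, rng_h)

    # one index-eligible stay per row; patient 1:1 with stay at this step
    hosp_idx = np.repeat(np.arange(cfg.n_hospitals), volumes)
    n = hosp_idx.size
    ages = _draw_ages(cfg, rng_p, n)
    male = rng_p.random(n) < cfg.p_male
    K = len(cfg.beta)
    comorb = (rng_p.random((n, K)) < np.asarray(cfg.covariate_prevalences)).astype(int)

    adm_date = win_start + rng_p.integers(0, max(1, win_len - 45), n)
    los = 1 + rng_p.poisson(4.0, n).clip(max=25)

    med_age = float(cfg.age_distribution["median"])
    eta = (
        cfg.mu
        + alphas[hosp_idx]
        + cfg.beta_age * (ages - med_age)
        + cfg.beta_sex * male
        + comorb @ np.asarray(cfg.beta)
    )
    p_outcome = expit(eta)
    y = rng_y.random(n) < p_outcome

    patient_ids = np.array([f"P{i + 1:06d}" for i in range(n)])
    sec_codes = [
        ";".join(c for c, z in zip(cfg.comorbidity_codes, row) if z)
        for row in comorb
    ]

    transfer = rng_f.random(n) < cfg.p_transfer
    other_hosp = rng_f.integers(0, cfg.n_hospitals, n)
    other_hosp = np.where(
        other_hosp == hosp_idx, (other_hosp + 1) % cfg.n_hospitals, other_hosp
    )
    transfer_gap = rng_f.integers(0, 2, n)          # 0 or 1 day: chains
    seg1_los = (1 + rng_f.poisson(2.0, n)).clip(max=10)

    rows: list[tuple] = []
    death_date = np.full(n, np.nan)

    if cfg.outcome == "mortality":
        death_offset = rng_y.integers(0, 31, n)     # days 0..30 from admission
        late_death = (~y) & (rng_y.random(n) < cfg.p_background_death)
        late_offset = rng_y.integers(31, 181, n)
        death_date[y] = adm_date[y] + death_offset[y]
        death_date[late_death] = adm_date[late_death] + late_offset[late_death]
        readmit = (~y) & (rng_f.random(n) < cfg.p_background_readmission)
    else:
        readmit = y.copy()
        bg_death = rng_y.random(n) < cfg.p_background_death
        bg_offset = rng_y.integers(0, 120, n)
        death_date[bg_death] = adm_date[bg_death] + bg_offset[bg_death]
        # a death before discharge would void readmission eligibility;
        # keep the measured process clean by pushing those deaths out
        clash = readmit & bg_death & (bg_offset <= los + 35)
        death_date[clash] = adm_date[clash] + los[clash] + 40

    # planned-readmission channel calibrated so the planned fraction of
    # emitted 30-day readmissions ≈ p_planned_readmission
    if cfg.outcome == "readmission":
        base_rate = float(np.mean(p_outcome))
    else:
        base_rate = cfg.p_background_readmission
    ppl = cfg.p_planned_readmission
    p_planned_event = min(0.5, base_rate * ppl / max(1e-12, 1.0 - ppl))
    planned_readmit = rng_f.random(n) < p_planned_event

    repeat_stay = rng_f.random(n) < cfg.p_repeat_index
    prior_stay = rng_f.random(n) < cfg.p_prior_admission
    obs_stay = rng_f.random(n) < cfg.p_observation_stay
    hospice = rng_f.random(n) < cfg.p_hospice
    short_enroll = rng_f.random(n) < cfg.p_short_enrollment

    readmit_gap = rng_f.integers(2, 31, n)          # days after discharge
    readmit_hosp = rng_f.integers(0, cfg.n_hospitals, n)
    readmit_los = (1 + rng_f.poisson(3.0, n)).clip(max=15)
    planned_gap = rng_f.integers(2, 31, n)
    repeat_gap = rng_f.integers(45, 121, n)
    prior_gap = rng_f.integers(35, 300, n)
    obs_gap = rng_f.integers(2, 31, n)
    hospice_back = rng_f.integers(0, 360, n)
    enroll_slack = rng_f.integers(0, 400, n)
    enroll_short = rng_f.integers(1, 100, n)
    repeat_y = rng_y.random(n) < p_outcome          # same case-mix, same hospital
    repeat_death_offset = rng_y.integers(0, 31, n)

    def emit(pid, hid, adm, dis, principal, secondary, procs, dispo, setting,
             age, sex):
        rows.append((pid, hid, int(adm), int(dis), principal, secondary,
                     procs, dispo, setting, age, sex))

    enr_rows = []
    truth_counts = np.zeros(cfg.n_hospitals, dtype=int)

    for i in range(n):
        pid = patient_ids[i]
        sex = "M" if male[i] else "F"
        age = float(ages[i])
        h_attr = hosp_idx[i]
        truth_counts[h_attr] += 1
        dd = death_date[i]
        adm0 = int(adm_date[i])

        if transfer[i]:
            # attributed hospital is the volume-assigned one: admitting
            # hospital for mortality, discharging hospital for readmission
            if cfg.outcome == "mortality":
                h1, h2 = h_attr, other_hosp[i]
            else:
                h1, h2 = other_hosp[i], h_attr
            dis1 = adm0 + int(seg1_los[i])
            adm2 = dis1 + int(transfer_gap[i])
            dis2 = adm2 + int(readmit_los[i])
            died_in_2 = (not np.isnan(dd)) and dd <= dis2
            if died_in_2 and dd < adm2:
                # death during first segment: no transfer after all
                dis1 = max(adm0, int(dd))
                emit(pid, hospital_ids[h1], adm0, dis1, cfg.condition,
                     sec_codes[i], OTHER_PROC, "died", "acute", age, sex)
                episode_discharge = dis1
                discharged_alive = False
            else:
                emit(pid, hospital_ids[h1], adm0, dis1, cfg.condition,
                     sec_codes[i], OTHER_PROC, "transfer_out", "acute", age, sex)
                if died_in_2:
                    dis2 = max(adm2, int(dd))
                emit(pid, hospital_ids[h2], adm2, dis2, "OTHER",
                     sec_codes[i], OTHER_PROC,
                     "died" if died_in_2 else "alive", "acute", age, sex)
                episode_discharge = dis2
                discharged_alive = not died_in_2
        else:
            dis0 = adm0 + int(los[i])
            died_in = (not np.isnan(dd)) and dd <= dis0
            if died_in:
                dis0 = max(adm0, int(dd))
            emit(pid, hospital_ids[h_attr], adm0, dis0, cfg.condition,
                 sec_codes[i], OTHER_PROC, "died" if died_in else "alive",
                 "acute", age, sex)
            episode_discharge = dis0
            discharged_alive = not died_in

        if discharged_alive and readmit[i]:
            radm = episode_discharge + int(readmit_gap[i])
            emit(pid, hospital_ids[readmit_hosp[i]], radm,
                 radm + int(readmit_los[i]), "OTHER", sec_codes[i],
                 OTHER_PROC, "alive", "acute", age, sex)
        if discharged_alive and planned_readmit[i]:
            radm = episode_discharge + int(planned_gap[i])
            h_pl = (readmit_hosp[i] + 1) % cfg.n_hospitals
            emit(pid, hospital_ids[h_pl], radm, radm + 2, "OTHER",
                 sec_codes[i], ALWAYS_PLANNED_PROC, "alive", "acute", age, sex)
        if discharged_alive and obs_stay[i]:
            oadm = episode_discharge + int(obs_gap[i])
            h_ob = (readmit_hosp[i] + 2) % cfg.n_hospitals
            emit(pid, hospital_ids[h_ob], oadm, oadm + 1, "OTHER",
                 sec_codes[i], OTHER_PROC, "alive", "observation", age, sex)
        if prior_stay[i]:
            padm = adm0 - int(prior_gap[i])
            emit(pid, hospital_ids[readmit_hosp[i]], padm,
                 padm + 2, "OTHER", sec_codes[i], OTHER_PROC, "alive",
                 "acute", age, sex)

        if repeat_stay[i] and discharged_alive and np.isnan(dd):
            radm = episode_discharge + int(repeat_gap[i])
            if radm < win_end - 5:
                rdis = radm + int(los[i])
                r_dd = np.nan
                if cfg.outcome == "mortality" and repeat_y[i]:
                    r_dd = radm + int(repeat_death_offset[i])
                    dd = r_dd
                died_in = (not np.isnan(r_dd)) and r_dd <= rdis
                if died_in:
                    rdis = max(radm, int(r_dd))
                emit(pid, hospital_ids[h_attr], radm, rdis, cfg.condition,
                     sec_codes[i], OTHER_PROC,
                     "died" if died_in else "alive", "acute", age, sex)
                truth_counts[h_attr] += 1
                if cfg.outcome == "readmission" and repeat_y[i] and not died_in:
                    radm2 = rdis + int(readmit_gap[i])
                    emit(pid, hospital_ids[readmit_hosp[i]], radm2,
                         radm2 + int(readmit_los[i]), "OTHER", sec_codes[i],
                         OTHER_PROC, "alive", "acute", age, sex)

        if short_enroll[i]:
            cov_start = adm0 - cfg.lookback_days + int(enroll_short[i])
        else:
            cov_start = adm0 - cfg.lookback_days - int(enroll_slack[i])
        cov_end = win_end + 100 if np.isnan(dd) else int(dd)
        spans = ""
        if hospice[i]:
            hs = adm0 - int(hospice_back[i])
            spans = f"{hs}:{hs + 60}"
        enr_rows.append((pid, int(cov_start), int(max(cov_end, cov_start)),
                         dd if not np.isnan(dd) else np.nan, spans))

    admissions = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "hospital_id", "admission_date", "discharge_date",
            "principal_condition", "secondary_conditions", "procedure_codes",
            "discharge_disposition", "setting", "age_at_admission", "sex",
        ],
    ).sort_values(
        ["patient_id", "admission_date", "hospital_id"], kind="mergesort"
    ).reset_index(drop=True)

    enrollment = pd.DataFrame(
        enr_rows,
        columns=["patient_id", "coverage_start", "coverage_end", "death_date",
                 "hospice_spans"],
    ).sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    enrollment["death_date"] = enrollment["death_date"].astype("Float64")

    truth = pd.DataFrame({
        "hospital_id": hospital_ids,
        "true_alpha": alphas,
        "n_index_stays": truth_counts,
    })

    return ClaimsDataset(admissions=admissions, enrollment=enrollment,
                         truth=truth, config=cfg)
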