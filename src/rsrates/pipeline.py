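"""End-to-end pipeline: simulate/load claims -> cohort -> fit -> bootstrap ->
trends -> national report, with every interface file written to an output
directory plus a run manifest (seed, config hash, library versions)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, CohortConfig, build_cohort
from .model import fit_hierarchical_logit
from .report import PERCENTILE_RANKS, averted_events, distribution_summary
from .simulate import ClaimsDataset, SimConfig, generate_population
from .standardize import (
    BootstrapConfig, ClusterBootstrap, categorize_table, national_crude_rate,
    hospital_rates,
)
from .trends import annual_rates, change_categories, gee_trend

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimConfig | None = field(default_factory=SimConfig)
    input_dir: str | None = None          # load claims CSVs instead of simulating
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    outdir: str = "rsrates_out"
    change_table: bool = False            # per-year bootstraps; slower
    plots: bool = False
    method: str = "laplace"
    n_quad: int = 9

    def config_hash(self) -> str:
        body = asdict(self)
        body.pop("outdir", None)        # hash the analysis, not its location
        payload = json.dumps(body, default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage '{name}' failed: {exc}"
                ) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the artifact bundle; returns a dict of
    the in-memory results keyed by stage."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    data = _load_or_simulate(cfg, out)
    results["claims"] = data

    cohort = _build(cfg, data, out)
    results["cohort"] = cohort

    fit, est = _fit(cfg, cohort, out)
    results["fit"] = fit

    crude = national_crude_rate(cohort.table)
    rates = hospital_rates(est, cohort.table, cohort.covariate_columns, crude)
    boot = _bootstrap(cfg, cohort, out)
    rates = rates.merge(boot, on="hospital_id", how="left")
    rates = categorize_table(
        rates, crude, cfg.cohort.min_cases_for_reporting
    )
    rates.to_csv(out / "hospital_rates.csv", index=False)
    results["rates"] = rates
    results["national_crude_rate_pct"] = crude

    panel = _trends(cfg, data, out, results)

    _report(cfg, rates, crude, out, results)

    if cfg.plots:
        _plot(rates, out)

    manifest = {
        "seed": cfg.sim.seed if cfg.sim else None,
        "config_hash": cfg.config_hash(),
        "rsrates_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_index_admissions": int(len(cohort.table)),
        "n_hospitals": int(cohort.table["hospital_id"].nunique())
        if len(cohort.table) else 0,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results


@_stage("simulate")
def _load_or_simulate(cfg, out):
    if cfg.input_dir:
        data = ClaimsDataset.from_csv(cfg.input_dir)
    else:
        data = generate_population(cfg.sim)
    data.to_csv(out / "claims")
    return data


@_stage("cohort")
def _build(cfg, data, out):
    cohort = build_cohort(data, cfg.cohort)
    cohort.table.to_csv(out / "cohort.csv", index=False)
    cohort.exclusions.to_csv(out / "exclusions.csv", index=False)
    return cohort


@_stage("fit")
def _fit(cfg, cohort, out):
    fit, est = fit_hierarchical_logit(
        cohort.table, cohort.covariate_columns,
        method=cfg.method, n_quad=cfg.n_quad,
    )
    fit.to_json(out / "model_fit.json")
    return fit, est


@_stage("bootstrap")
def _bootstrap(cfg, cohort, out):
    bt = ClusterBootstrap(cfg.bootstrap)
    boot = bt.run(cohort.table, cohort.covariate_columns)
    with open(out / "bootstrap_diagnostics.json", "w") as fh:
        json.dump(
            {"n_dropped": bt.n_dropped_,
             "appearances": {str(k): int(v) for k, v in bt.appearances_.items()}},
            fh, indent=2,
        )
    return boot


@_stage("trends")
def _trends(cfg, data, out, results):
    panel = annual_rates(data, cfg.cohort, method=cfg.method, n_quad=cfg.n_quad)
    panel.to_csv(out / "annual_rates.csv", index=False)
    results["annual_panel"] = panel
    if panel["period"].nunique() >= 2:
        trend = gee_trend(panel)
        trend.to_json(out / "trend_result.json")
        results["trend"] = trend
    if cfg.change_table and panel["period"].nunique() >= 2:
        periods = sorted(panel["period"].unique())
        cats = {}
        for per in (periods[0], periods[-1]):
            from dataclasses import replace
            start = cfg.cohort.window[0]
            win = (start + (per - 1) * cfg.cohort.period_days,
                   start + per * cfg.cohort.period_days)
            ccfg = replace(cfg.cohort, window=win)
            cohort_k = build_cohort(data, ccfg)
            fit, est = fit_hierarchical_logit(
                cohort_k.table, cohort_k.covariate_columns, method=cfg.method
            )
            crude_k = national_crude_rate(cohort_k.table)
            rates_k = hospital_rates(
                est, cohort_k.table, cohort_k.covariate_columns, crude_k
            )
            boot_k = ClusterBootstrap(cfg.bootstrap).run(
                cohort_k.table, cohort_k.covariate_columns
            )
            rates_k = rates_k.merge(boot_k, on="hospital_id", how="left")
            cats[per] = categorize_table(
                rates_k, crude_k, cfg.cohort.min_cases_for_reporting
            )
        tab = change_categories(
            cats[periods[0]], cats[periods[-1]],
            cfg.cohort.min_cases_for_reporting,
        )
        tab.table().to_csv(out / "change_table.csv", index=False)
        results["change_table"] = tab
    return panel


@_stage("report")
def _report(cfg, rates, crude, out, results):
    reported = rates[
        (rates["category"] != "not_reported")
        & rates["boot_variance"].notna()
    ]
    summary = distribution_summary(
        reported["rate_pct"], reported["boot_variance"]
    )
    rows = [("weighted_mean", summary.weighted_mean),
            ("weighted_sd", summary.weighted_sd)]
    rows += [(str(r), summary.percentiles[r]) for r in PERCENTILE_RANKS]
    pd.DataFrame(rows, columns=["statistic", "value_pct"]).to_csv(
        out / "distribution_summary.csv", index=False
    )
    averted = averted_events(
        reported["rate_pct"], reported["n_cases"], reported["boot_variance"]
    )
    (out / "report.json").write_text(json.dumps({
        "national_crude_rate_pct": crude,
        "weighted_mean_pct": summary.weighted_mean,
        "weighted_sd_pct": summary.weighted_sd,
        "median_pct": summary.percentiles[50],
        "p5_p95_gap_pct": summary.gap(5, 95),
        "averted_events": averted,
        "n_hospitals_reported": summary.n_hospitals,
    }, indent=2))
    results["summary"] = summary
    results["averted_events"] = averted


def _plot(rates, out):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    reported = rates[rates["category"] != "not_reported"]
    reported["rate_pct"].plot.density(ax=ax)
    ax.set_xlabel("risk-standardized rate (%)")
    ax.set_title("Hospital rate distribution")
    fig.tight_layout()
    fig.savefig(out / "rate_density.png", dpi=120)
    plt.close(fig)
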