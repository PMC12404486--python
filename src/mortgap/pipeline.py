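"""End-to-end pipeline: simulate -> fit -> project -> scenarios -> statistics.

A single :class:`RunConfig` drives every stage; outputs land in a run
directory with a manifest recording the seed, config hash and package
version so any run can be reproduced bit-for-bit at the draws level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import shift_covariates
from .data_io import (MortalityTable, SchemaError, esp2013_weights,
                      write_mortality_table)
from .model import (McmcConfig, ModelSpec, PosteriorDraws, sample_posterior,
                    select_model)
from .projection import (ProjectionResult, estimate_drift, expected_deaths,
                         project_rates, project_year_effects)
from .stats import asmr_series, observed_expected_ratio, scenario_excess
from .synthetic import (CovariateSeries, TruthParams, make_fixture,
                        simulate_deaths, simulate_exposures)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

DEFAULT_CANDIDATE_INTERACTIONS = (
    ("age", "year"), ("deprivation", "year"), ("region", "deprivation"),
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, YAML-serialisable."""

    preset: str = "tiny"                    # tiny | paper_scale
    cause: str = "LC"
    sex: str = "M"
    seed: int = 0
    horizon_start: int = 2019
    horizon_end: int = 2036
    scenario_delays: tuple[int, ...] = (1, 3, 6)   # months
    scenario_from_year: int = 2020
    interval_level: float = 0.95
    select: bool = False                    # DIC selection over candidates
    mcmc_chains: int = 2
    mcmc_iterations: int = 2000
    mcmc_burn_in: int = 1000
    mcmc_thin: int = 2
    ns_lag_years: int = 0
    out_dir: str = "runs/latest"

    @property
    def base_year(self) -> int:
        return 2018

    def mcmc(self) -> McmcConfig:
        return McmcConfig(chains=self.mcmc_chains,
                          iterations=self.mcmc_iterations,
                          burn_in=self.mcmc_burn_in, thin=self.mcmc_thin,
                          seed=self.seed)

    def model_spec(self, interactions: tuple = ()) -> ModelSpec:
        mains = ("age", "year", "deprivation", "region", "ns")
        if self.cause == "LC":
            mains = mains + ("aad",)
        return ModelSpec(cause=self.cause, sex=self.sex, main_effects=mains,
                         interactions=interactions, base_year=self.base_year)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["scenario_delays"] = list(self.scenario_delays)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "scenario_delays" in d:
            d["scenario_delays"] = tuple(d["scenario_delays"])
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def validate_config(config: RunConfig) -> dict:
    """Collect configuration violations; never raises.

    Returns {"errors": [...], "warnings": [...]}; an empty error list means
    the config is runnable.
    """
    errors, warns = [], []
    if config.preset not in ("tiny", "paper_scale"):
        errors.append(f"unknown preset {config.preset!r}")
    if config.cause not in ("LC", "BC"):
        errors.append(f"unknown cause {config.cause!r}")
    if config.cause == "BC" and config.sex != "F":
        errors.append("breast-cancer runs require sex 'F'")
    if config.horizon_start != config.base_year + 1:
        errors.append(
            f"projection horizon must start the year after the last fitted "
            f"year ({config.base_year}); got {config.horizon_start}"
        )
    if config.horizon_end < config.horizon_start:
        errors.append("horizon_end before horizon_start")
    if any(d < 0 for d in config.scenario_delays):
        errors.append("diagnosis delays must be >= 0 months")
    if config.cause == "BC" and config.scenario_delays:
        errors.append(
            "diagnosis-delay scenarios are only defined for lung cancer "
            "(the AAD covariate is excluded from breast-cancer models)"
        )
    if not 0 < config.interval_level < 1:
        errors.append("interval_level must lie in (0, 1)")
    if config.mcmc_burn_in >= config.mcmc_iterations:
        errors.append("mcmc_burn_in must be < mcmc_iterations")
    if config.mcmc_chains < 2:
        warns.append("fewer than 2 chains: convergence diagnostics disabled")
    if config.scenario_from_year < config.horizon_start:
        errors.append("scenario_from_year precedes the projection horizon")
    return {"errors": errors, "warnings": warns}


def _extend_truth_kappa(truth: TruthParams, years: Sequence[int],
                        seed: int) -> TruthParams:
    """Continue the ground-truth kappa walk past the base year."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3307]))
    kappa = dict(truth.kappa)
    last = max(kappa)
    for year in sorted(int(y) for y in years):
        if year in kappa:
            continue
        for y in range(last + 1, year + 1):
            if y not in kappa:
                kappa[y] = (kappa[y - 1] + truth.delta
                            + truth.sigma_kappa * rng.standard_normal())
        last = max(last, year)
    return replace(truth, kappa=kappa)


def baseline_horizon_covariates(covariates: CovariateSeries,
                                base_year: int) -> CovariateSeries:
    """Baseline projection covariates: AAD frozen at its base-year value.

    NS prevalence keeps following its (simulated or trend-extrapolated)
    series; AAD is held at the last observed value unless a scenario
    shifts it.
    """
    aad = covariates.aad.copy()
    base = (aad[aad["year"] == base_year]
            .set_index(["region", "sex"])["aad_years"])
    future = aad["year"] > base_year
    key = list(zip(aad.loc[future, "region"], aad.loc[future, "sex"]))
    aad.loc[future, "aad_years"] = [base[k] for k in key]
    return CovariateSeries(covariates.ns.copy(), aad, covariates.aad_band)


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    truth: TruthParams
    covariates: CovariateSeries
    table: MortalityTable
    draws: PosteriorDraws
    baseline: ProjectionResult
    scenarios: dict[int, ProjectionResult] = field(default_factory=dict)
    excess: dict[int, object] = field(default_factory=dict)
    selection: dict | None = None
    ratios: pd.DataFrame | None = None
    out_dir: Path | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage from one config; see the run directory's manifest."""
    report = validate_config(config)
    if report["errors"]:
        raise SchemaError("; ".join(report["errors"]))
    for w in report["warnings"]:
        warnings.warn(w, stacklevel=2)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- simulate ---------------------------------------------------------
    truth, covariates, table = make_fixture(config.preset, seed=config.seed,
                                            cause=config.cause,
                                            sex=config.sex)
    write_mortality_table(table, out / "synthetic_table.csv")

    # --- fit (optionally with DIC selection) ------------------------------
    selection = None
    if config.select:
        candidates = [config.model_spec()] + [
            config.model_spec(interactions=(pair,))
            for pair in DEFAULT_CANDIDATE_INTERACTIONS
        ]
        selection = select_model(candidates, table, covariates,
                                 config.mcmc())
        spec = selection["best"]
        draws = sample_posterior(spec, table, covariates, config.mcmc())
    else:
        spec = config.model_spec()
        draws = sample_posterior(spec, table, covariates, config.mcmc())

    # --- project baseline -------------------------------------------------
    horizon = range(config.horizon_start, config.horizon_end + 1)
    delta, sigma_kappa = estimate_drift(draws.kappa_draws())
    kappa_paths = project_year_effects(delta, sigma_kappa, horizon,
                                       seed=config.seed,
                                       base_year=config.base_year)
    grid = table.data
    horizon_exposures = simulate_exposures(
        config.cause, config.sex, years=horizon,
        age_groups=tuple(sorted(grid["age_group"].unique())),
        regions=tuple(grid["region"].unique()),
        quintiles=tuple(sorted(grid["deprivation"].unique())))
    base_cov = baseline_horizon_covariates(covariates, config.base_year)
    baseline = project_rates(draws, kappa_paths, base_cov,
                             exposures=horizon_exposures,
                             horizon_years=horizon, seed=config.seed,
                             scenario="baseline")
    baseline.summaries(config.interval_level).to_csv(
        out / "projection_baseline.csv", index=False)

    # --- scenarios (lung cancer only) -------------------------------------
    scenarios: dict[int, ProjectionResult] = {}
    excess: dict[int, object] = {}
    if config.cause == "LC":
        for delay in config.scenario_delays:
            scen_cov = shift_covariates(base_cov, delay,
                                        config.scenario_from_year)
            scen = project_rates(draws, kappa_paths, scen_cov,
                                 exposures=horizon_exposures,
                                 horizon_years=horizon, seed=config.seed,
                                 scenario=f"delay_{delay}m")
            scenarios[delay] = scen
            exc = scenario_excess(baseline, scen)
            excess[delay] = exc
            exc.summary(by=("region", "deprivation"),
                        level=config.interval_level).to_csv(
                out / f"excess_delay_{delay}m.csv", index=False)

    # --- pandemic-period observed/expected ratios -------------------------
    ratio_years = [y for y in (2020, 2021, 2022)
                   if config.horizon_start <= y <= config.horizon_end]
    ratios = None
    if ratio_years:
        truth_ext = _extend_truth_kappa(truth, ratio_years, config.seed)
        reg_exp = horizon_exposures[
            horizon_exposures["year"].isin(ratio_years)].reset_index(drop=True)
        registered = simulate_deaths(truth_ext, reg_exp, covariates,
                                     seed=config.seed + 1)
        mask = baseline.frame["year"].isin(ratio_years).to_numpy()
        exp_draws = expected_deaths(baseline)[:, mask]
        sub = baseline.frame.loc[mask].reset_index(drop=True)
        reg_sorted = registered.sorted().data
        rows = []
        for age, grp in sub.groupby("age_group", sort=True):
            cols = grp.index.to_numpy()
            reg_count = reg_sorted.loc[
                reg_sorted["age_group"] == age, "deaths"].sum()
            res = observed_expected_ratio(reg_count,
                                          exp_draws[:, cols],
                                          level=config.interval_level)
            res.pop("ratio_draws")
            rows.append({"age_group": age, **res})
        total = observed_expected_ratio(reg_sorted["deaths"].sum(),
                                        exp_draws,
                                        level=config.interval_level)
        total.pop("ratio_draws")
        rows.append({"age_group": "all", **total})
        ratios = pd.DataFrame(rows)
        ratios.to_csv(out / "observed_expected_ratios.csv", index=False)

    # --- disparity statistics ---------------------------------------------
    weights = esp2013_weights(tuple(sorted(grid["age_group"].unique(),
                                           key=lambda s: s.split("-")[0])))
    asmr_by_dep = asmr_series(baseline, weights,
                              by=("year", "region", "deprivation"),
                              level=config.interval_level)
    asmr_by_dep.to_csv(out / "asmr_region_deprivation.csv", index=False)

    quintiles = sorted(grid["deprivation"].unique())
    q1, q5 = quintiles[0], quintiles[-1]
    gap_rows = []
    frame = baseline.frame
    for (year, region), grp in frame.groupby(["year", "region"], sort=True):
        per_q = {}
        for q in (q1, q5):
            sel = grp.index[grp["deprivation"] == q].to_numpy()
            ages = frame.loc[sel, "age_group"].tolist()
            per_age = {a: baseline.rate_draws[:, s]
                       for a, s in zip(ages, sel)}
            from .stats import asmr as _asmr
            per_q[q] = _asmr(per_age, weights)
        from .stats import relative_gap
        g = relative_gap(per_q[q1], per_q[q5])
        a = (1 - config.interval_level) / 2
        gap_rows.append({
            "year": year, "region": region,
            "gap_mean": float(g.mean()),
            "gap_lo": float(np.quantile(g, a)),
            "gap_hi": float(np.quantile(g, 1 - a)),
        })
    gap = pd.DataFrame(gap_rows)
    gap.to_csv(out / "relative_deprivation_gap.csv", index=False)

    # --- manifest ----------------------------------------------------------
    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "spec": repr(spec),
        "n_draws": draws.n_draws,
        "max_rhat": draws.diagnostics.get("max_rhat"),
        "selection": (None if selection is None else [
            {"candidate": t["candidate"], "dic": t["dic"],
             "n_params": t["n_params"]} for t in selection["trace"]]),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    return PipelineResult(config=config, truth=truth, covariates=covariates,
                          table=table, draws=draws, baseline=baseline,
                          scenarios=scenarios, excess=excess,
                          selection=selection, ratios=ratios, out_dir=out)
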