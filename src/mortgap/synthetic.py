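"""Synthetic stratified mortality data with known ground truth.

The national registry extract behind this kind of analysis (cause-specific
death registrations by region and income-deprivation band) is access
restricted, so every pipeline stage here is exercised against simulated
tables whose generative parameters are known exactly.  The generator mirrors
the real data's structure: nine English regions x five deprivation quintiles
x sexes x 5-year age bands x years 2001-2018, Poisson death counts with a
lognormal stratum-level heterogeneity term, a declining male lung-cancer
trend, a levelled female lung-cancer trend in deprived groups, a declining
breast-cancer trend, and a monotone deprivation gradient.

Seed handling: one global seed is expanded into per-purpose substreams via
``numpy.random.SeedSequence(seed).spawn`` — child 0 drives covariates,
child 1 drives death counts — so partial re-runs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    BC_AGE_GROUPS,
    LC_AGE_GROUPS,
    REGIONS,
    MortalityTable,
    SchemaError,
    age_groups_for,
)

__all__ = [
    "TruthParams",
    "CovariateSeries",
    "default_truth",
    "simulate_covariates",
    "simulate_exposures",
    "simulate_deaths",
    "truth_eta",
    "make_fixture",
]

FIT_YEARS = tuple(range(2001, 2019))
HORIZON_YEARS = tuple(range(2019, 2037))

#: Approximate regional shares of the English population.
REGION_POP_SHARE = {
    "north_east": 0.047, "north_west": 0.131, "yorkshire_humber": 0.097,
    "east_midlands": 0.086, "west_midlands": 0.105, "east": 0.111,
    "london": 0.158, "south_east": 0.165, "south_west": 0.100,
}

#: Share of the (single-sex) population in each 5-year band.
AGE_POP_SHARE = {
    "35-39": 0.066, "40-44": 0.064, "45-49": 0.063, "50-54": 0.061,
    "45-54": 0.124, "55-59": 0.056, "60-64": 0.051, "65-69": 0.047,
    "70-74": 0.039, "75-79": 0.030, "80-84": 0.021, "85-89": 0.012,
}

ENGLAND_POP = 56_000_000
ANNUAL_POP_GROWTH = 0.005

# age-specific log death rates (per person-year) anchoring the synthetic
# baseline near published English cause-specific magnitudes
_LC_LOG_RATES = {
    "45-54": math.log(25e-5), "55-59": math.log(90e-5),
    "60-64": math.log(160e-5), "65-69": math.log(270e-5),
    "70-74": math.log(400e-5), "75-79": math.log(500e-5),
    "80-84": math.log(550e-5), "85-89": math.log(500e-5),
}
_BC_LOG_RATES = {
    "35-39": math.log(5e-5), "40-44": math.log(10e-5),
    "45-49": math.log(18e-5), "50-54": math.log(28e-5),
    "55-59": math.log(40e-5), "60-64": math.log(55e-5),
    "65-69": math.log(70e-5), "70-74": math.log(90e-5),
    "75-79": math.log(120e-5), "80-84": math.log(160e-5),
    "85-89": math.log(220e-5),
}


@dataclass
class CovariateSeries:
    """Non-smoker prevalence and average age-at-diagnosis series.

    ``ns``  : DataFrame (age_group, sex, year, prevalence), prevalence in [0,1].
    ``aad`` : DataFrame (region, sex, year, aad_years), in years of age.
    """

    ns: pd.DataFrame
    aad: pd.DataFrame
    aad_band: tuple[float, float] = (50.0, 85.0)

    def __post_init__(self) -> None:
        p = self.ns["prevalence"]
        if ((p < 0) | (p > 1)).any():
            raise SchemaError("NS prevalence outside [0, 1]")
        a = self.aad["aad_years"]
        lo, hi = self.aad_band
        if ((a < lo) | (a > hi)).any():
            raise SchemaError(f"AAD outside declared band [{lo}, {hi}]")

    def ns_lookup(self) -> dict[tuple[str, str, int], float]:
        return {(r.age_group, r.sex, int(r.year)): float(r.prevalence)
                for r in self.ns.itertuples(index=False)}

    def aad_lookup(self) -> dict[tuple[str, str, int], float]:
        return {(r.region, r.sex, int(r.year)): float(r.aad_years)
                for r in self.aad.itertuples(index=False)}

    def copy(self) -> "CovariateSeries":
        return CovariateSeries(self.ns.copy(), self.aad.copy(), self.aad_band)


@dataclass
class TruthParams:
    """Ground-truth generative parameters for one cause/sex model.

    The year effect ``kappa`` is a realised random walk with drift ``delta``
    and innovation s.d. ``sigma_kappa``, anchored so kappa[base_year] == 0.
    Categorical effect vectors are sum-to-zero; the deprivation gradient is
    non-increasing from quintile 1 (most deprived) to 5 when monotone.
    """

    cause: str
    sex: str
    intercept: float
    age_effects: dict[str, float]
    kappa: dict[int, float]
    delta: float
    sigma_kappa: float
    gamma: dict[int, float]          # deprivation quintile -> effect
    rho: dict[str, float]            # region -> effect
    beta_aad: float
    beta_ns: float
    dep_year_slopes: dict[int, float] = field(default_factory=dict)
    sigma_eps: float = 0.05
    base_year: int = 2018
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cause == "BC" and self.sex != "F":
            raise SchemaError("breast-cancer truth requires sex 'F'")
        if self.sigma_eps < 0 or self.sigma_kappa < 0:
            raise SchemaError("scale parameters must be non-negative")
        for name, vec in (("age_effects", self.age_effects),
                          ("gamma", self.gamma), ("rho", self.rho)):
            if abs(sum(vec.values())) > 1e-12:
                raise SchemaError(f"{name} not sum-to-zero")
        if abs(self.kappa[self.base_year]) > 1e-12:
            raise SchemaError("kappa not anchored at base year")

    def gamma_contrasts(self) -> dict[int, float]:
        """Deprivation effects relative to the least deprived quintile."""
        ref = self.gamma[max(self.gamma)]
        return {q: g - ref for q, g in self.gamma.items()}


def _anchored_rw(rng: np.random.Generator, years: Sequence[int], delta: float,
                 sigma: float, base_year: int) -> dict[int, float]:
    steps = delta + sigma * rng.standard_normal(len(years) - 1)
    path = np.concatenate([[0.0], np.cumsum(steps)])
    path -= path[list(years).index(base_year)]
    return dict(zip(years, path))


def default_truth(cause: str, sex: str, seed: int = 0) -> TruthParams:
    """Documented default ground truth for one cause/sex combination.

    Male lung cancer declines (drift < 0); female lung cancer is level on
    average (drift ~ 0) with a deprivation-year interaction that lets the
    affluent quintiles improve while the deprived stagnate; breast cancer
    declines.  The deprivation gradient is monotone (most deprived worst)
    and strong for lung cancer, mild for breast cancer.
    """
    if cause not in ("LC", "BC"):
        raise SchemaError(f"unknown cause {cause!r}")
    if cause == "BC" and sex != "F":
        raise SchemaError("no breast-cancer model for men")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 797]))
    years = FIT_YEARS
    if cause == "LC":
        log_rates = dict(_LC_LOG_RATES)
        if sex == "F":
            log_rates = {a: v - 0.25 for a, v in log_rates.items()}
        mean_lr = float(np.mean(list(log_rates.values())))
        age_effects = {a: v - mean_lr for a, v in log_rates.items()}
        gamma = {1: 0.35, 2: 0.15, 3: 0.0, 4: -0.2, 5: -0.3}
        rho = {"north_east": 0.12, "north_west": 0.10,
               "yorkshire_humber": 0.08, "east_midlands": 0.02,
               "west_midlands": 0.0, "east": -0.06, "london": -0.10,
               "south_east": -0.08, "south_west": -0.08}
        beta_aad, beta_ns = 0.15, -1.5
        if sex == "M":
            delta, dep_year = -0.025, {}
        else:
            delta = 0.0
            dep_year = {1: 0.010, 2: 0.005, 3: 0.0, 4: -0.005, 5: -0.010}
    else:
        mean_lr = float(np.mean(list(_BC_LOG_RATES.values())))
        age_effects = {a: v - mean_lr for a, v in _BC_LOG_RATES.items()}
        gamma = {1: 0.10, 2: 0.05, 3: 0.0, 4: -0.05, 5: -0.10}
        rho = {"north_east": 0.04, "north_west": 0.03,
               "yorkshire_humber": 0.03, "east_midlands": 0.01,
               "west_midlands": 0.0, "east": -0.02, "london": -0.04,
               "south_east": -0.03, "south_west": -0.02}
        beta_aad, beta_ns = 0.0, -0.2
        delta, dep_year = -0.015, {}
    sigma_kappa = 0.008
    kappa = _anchored_rw(rng, years, delta, sigma_kappa, 2018)
    return TruthParams(
        cause=cause, sex=sex, intercept=mean_lr, age_effects=age_effects,
        kappa=kappa, delta=delta, sigma_kappa=sigma_kappa, gamma=gamma,
        rho=rho, beta_aad=beta_aad, beta_ns=beta_ns,
        dep_year_slopes=dep_year, sigma_eps=0.05, base_year=2018,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Covariates

def simulate_covariates(truth: TruthParams,
                        years: Sequence[int] = FIT_YEARS + HORIZON_YEARS,
                        age_groups: Sequence[str] | None = None,
                        regions: Sequence[str] = REGIONS,
                        seed: int | None = None,
                        ns_noise_sd: float = 0.05,
                        aad_noise_sd: float = 0.15) -> CovariateSeries:
    """Simulate non-smoker prevalence and age-at-diagnosis series.

    NS prevalence follows a logistic-in-year trend per (age band, sex) with
    age-varying slopes (younger bands rise faster, men faster and more
    uniformly than women); noise is added on the logit scale so bounds hold
    for every seed and a zero noise s.d. gives an exactly monotone series.
    AAD drifts slowly upward per region around a cause-typical level with
    region-year fluctuations.  The age- and region-varying slopes give the
    covariates the non-additive year structure that separates them from a
    free year effect at model-fitting time.
    """
    if len(years) == 0:
        raise SchemaError("empty covariate grid")
    if age_groups is None:
        age_groups = age_groups_for(truth.cause)
    seed = truth.seed if seed is None else int(seed)
    children = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(children[0])

    years = sorted(int(y) for y in years)
    ns_rows = []
    for i, age in enumerate(age_groups):
        # older bands: lower prevalence and slower rise
        base_logit = 0.3 - 0.10 * i
        slope = (0.040 if truth.sex == "M" else 0.028) * (1.0 - 0.07 * i)
        noise = ns_noise_sd * rng.standard_normal(len(years))
        for j, year in enumerate(years):
            z = base_logit + slope * (year - 1981) + noise[j]
            ns_rows.append((age, truth.sex, year, 1.0 / (1.0 + math.exp(-z))))
    ns = pd.DataFrame(ns_rows,
                      columns=["age_group", "sex", "year", "prevalence"])

    base_aad = 71.0 if truth.cause == "LC" else 63.0
    aad_rows = []
    for k, region in enumerate(regions):
        offset = 0.8 * math.sin(1.0 + 2.1 * k)      # fixed regional offsets
        drift = 0.015 + 0.004 * math.cos(0.7 * k)   # region-specific drift
        wiggle = aad_noise_sd * rng.standard_normal(len(years))
        for j, year in enumerate(years):
            a = base_aad + offset + drift * (year - years[0]) + wiggle[j]
            aad_rows.append((region, truth.sex, year, a))
    aad = pd.DataFrame(aad_rows,
                       columns=["region", "sex", "year", "aad_years"])
    return CovariateSeries(ns, aad)


# ---------------------------------------------------------------------------
# Exposures and deaths

def simulate_exposures(cause: str, sex: str,
                       years: Sequence[int] = FIT_YEARS,
                       age_groups: Sequence[str] | None = None,
                       regions: Sequence[str] = REGIONS,
                       quintiles: Sequence[int] = (1, 2, 3, 4, 5),
                       ) -> pd.DataFrame:
    """Deterministic person-years exposures on a full stratification grid.

    Built from regional population shares, a single-sex age pyramid, equal
    quintile shares and mild exponential growth — deterministic so that all
    sampling variability in a synthetic table comes from the death counts.
    Returns a frame with the stratum key columns plus ``exposure``.
    """
    if age_groups is None:
        age_groups = age_groups_for(cause)
    rows = []
    for age in age_groups:
        for year in years:
            growth = (1.0 + ANNUAL_POP_GROWTH) ** (year - 2001)
            for region in regions:
                for q in quintiles:
                    e = (ENGLAND_POP * 0.5 * REGION_POP_SHARE[region]
                         * AGE_POP_SHARE[age] * 0.2 * growth)
                    rows.append((cause, sex, age, int(year), region, int(q), e))
    return pd.DataFrame(rows, columns=["cause", "sex", "age_group", "year",
                                       "region", "deprivation", "exposure"])


def truth_eta(truth: TruthParams, frame: pd.DataFrame,
              covariates: CovariateSeries,
              aad_center: float | None = None,
              ns_center: float | None = None) -> np.ndarray:
    """Ground-truth log-rate eta for each row of a stratum frame.

    eta = b0 + alpha_age + kappa_year + gamma_q + rho_r
          + beta_aad (a - a_bar) + beta_ns (p - p_bar)
          + slope_q (year - base_year)   [deprivation-year interaction]

    Covariates enter centred; by default the centring constants are the
    means over the frame itself (the fitting window).
    """
    ns_map = covariates.ns_lookup()
    aad_map = covariates.aad_lookup()
    try:
        aad = np.array([aad_map[(r.region, r.sex, int(r.year))]
                        for r in frame.itertuples(index=False)])
        ns = np.array([ns_map[(r.age_group, r.sex, int(r.year))]
                       for r in frame.itertuples(index=False)])
    except KeyError as exc:
        raise SchemaError(f"covariate missing for cell {exc.args[0]}") from exc
    if aad_center is None:
        aad_center = float(aad.mean())
    if ns_center is None:
        ns_center = float(ns.mean())
    eta = np.full(len(frame), truth.intercept)
    eta += frame["age_group"].map(truth.age_effects).to_numpy(float)
    eta += frame["year"].map(truth.kappa).to_numpy(float)
    eta += frame["deprivation"].map(truth.gamma).to_numpy(float)
    eta += frame["region"].map(truth.rho).to_numpy(float)
    eta += truth.beta_aad * (aad - aad_center)
    eta += truth.beta_ns * (ns - ns_center)
    if truth.dep_year_slopes:
        slopes = frame["deprivation"].map(truth.dep_year_slopes).to_numpy(float)
        eta += slopes * (frame["year"].to_numpy(int) - truth.base_year)
    return eta


def simulate_deaths(truth: TruthParams, exposures: pd.DataFrame,
                    covariates: CovariateSeries, seed: int | None = None,
                    ) -> MortalityTable:
    """Draw Poisson-lognormal death counts on an exposure grid.

    D ~ Poisson(E exp(eta + eps)), eps ~ Normal(0, sigma_eps^2) independently
    per stratum cell.  Reproducible: the given (or truth) seed's substream 1
    drives both the heterogeneity draws and the Poisson counts.
    """
    if (exposures["exposure"] <= 0).any():
        raise SchemaError("exposures must be positive on the full grid")
    seed = truth.seed if seed is None else int(seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    eta = truth_eta(truth, exposures, covariates)
    eps = (truth.sigma_eps * rng.standard_normal(len(exposures))
           if truth.sigma_eps > 0 else np.zeros(len(exposures)))
    lam = exposures["exposure"].to_numpy(float) * np.exp(eta + eps)
    deaths = rng.poisson(lam)
    df = exposures.copy()
    df["deaths"] = deaths.astype(int)
    cols = ["cause", "sex", "age_group", "year", "region", "deprivation",
            "deaths", "exposure"]
    return MortalityTable(df[cols])


# ---------------------------------------------------------------------------
# Fixtures

TINY_REGIONS = ("north_east", "london")
TINY_QUINTILES = (1, 5)
TINY_YEARS = tuple(range(2013, 2019))


def make_fixture(preset: str, seed: int = 0, cause: str = "LC",
                 sex: str = "M", truth: TruthParams | None = None,
                 ) -> tuple[TruthParams, CovariateSeries, MortalityTable]:
    """Bundle (truth, covariates, table) for a named problem size.

    ``tiny``        : 2 regions x 2 quintiles x 3 age groups x 6 years
                      (72 cells; fits in seconds).
    ``paper_scale`` : 9 regions x 5 quintiles x full age list x 2001-2018.
    """
    if preset not in ("tiny", "paper_scale"):
        raise SchemaError(f"unknown preset {preset!r}")
    if truth is None:
        truth = default_truth(cause, sex, seed=seed)
    else:
        cause, sex = truth.cause, truth.sex
    if preset == "tiny":
        regions, quintiles = TINY_REGIONS, TINY_QUINTILES
        age_groups = ("60-64", "70-74", "80-84")
        years = TINY_YEARS
    else:
        regions, quintiles = REGIONS, (1, 2, 3, 4, 5)
        age_groups = age_groups_for(cause)
        years = FIT_YEARS
    # covariates extend through the projection horizon for either preset
    cov_years = tuple(years) + tuple(range(max(years) + 1, 2037))
    covariates = simulate_covariates(truth, years=cov_years,
                                     age_groups=age_groups, regions=regions,
                                     seed=seed)
    exposures = simulate_exposures(cause, sex, years=years,
                                   age_groups=age_groups, regions=regions,
                                   quintiles=quintiles)
    table = simulate_deaths(truth, exposures, covariates, seed=seed)
    return truth, covariates, table
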