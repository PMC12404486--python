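"""Mortality projection by random walk with drift on the year effect.

The fitted year effects kappa_2001..kappa_2018 (anchored at the baseline
year 2018) are extrapolated per posterior draw as a random walk with drift:
the drift is the mean of the draw's successive kappa differences and the
innovation s.d. their sample standard deviation, so parameter uncertainty
propagates draw by draw.  Age, deprivation, region and covariate effects are
held at their fitted values over the horizon; interactions involving the
year effect vanish at the anchor year and are therefore frozen out of the
projection.  Future cells receive fresh lognormal heterogeneity draws
(predictive semantics), and future covariates default to last-observed AAD
and trend-extrapolated NS prevalence unless a scenario shifts them.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import SchemaError
from .model import DesignInfo, PosteriorDraws, _contrast_matrix
from .synthetic import CovariateSeries

__all__ = [
    "ProjectionResult",
    "estimate_drift",
    "drift_posterior",
    "project_year_effects",
    "project_rates",
    "expected_deaths",
    "build_horizon_frame",
]


@dataclass
class ProjectionResult:
    """Per-stratum-year rate draws over a projection horizon (or fit window).

    ``frame`` holds one row per (age group, region, deprivation, year) with
    its exposure; ``rate_draws`` is (n_draws, n_rows) of death rates m.
    """

    frame: pd.DataFrame
    rate_draws: np.ndarray
    scenario: str = "baseline"
    seed: int = 0
    spec_hash: str = ""

    def __post_init__(self) -> None:
        if self.rate_draws.shape[1] != len(self.frame):
            raise SchemaError("rate draws misaligned with stratum frame")
        if np.any(self.rate_draws <= 0):
            raise SchemaError("projected rates must be positive")

    @property
    def n_draws(self) -> int:
        return self.rate_draws.shape[0]

    def summaries(self, level: float = 0.95) -> pd.DataFrame:
        a = (1.0 - level) / 2.0
        out = self.frame.copy()
        out["mean"] = self.rate_draws.mean(axis=0)
        out["lo"] = np.quantile(self.rate_draws, a, axis=0)
        out["hi"] = np.quantile(self.rate_draws, 1.0 - a, axis=0)
        out["scenario"] = self.scenario
        return out


def estimate_drift(kappa_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw drift and innovation s.d. of the year-effect random walk.

    For each posterior draw, delta is the mean of successive kappa
    differences and sigma_kappa their sample standard deviation, so that
    drift uncertainty flows through the draws.
    """
    kappa_draws = np.atleast_2d(np.asarray(kappa_draws, dtype=float))
    if kappa_draws.shape[1] < 3:
        raise SchemaError("drift estimation needs >= 3 years of kappa")
    diffs = np.diff(kappa_draws, axis=1)
    delta = diffs.mean(axis=1)
    sigma = diffs.std(axis=1, ddof=1)
    return delta, sigma


def drift_posterior(kappa_draws: np.ndarray, seed: int = 0) -> np.ndarray:
    """Per-draw samples from the drift's conditional posterior.

    Given one kappa path, the random-walk drift has conditional posterior
    Normal(mean diff, sigma_kappa^2 / (T-1)) under a flat prior; mixing that
    over posterior kappa paths propagates both path and estimation
    uncertainty.  A deterministic (exactly linear) path has zero innovation
    s.d. and so returns its slope exactly.
    """
    delta, sigma = estimate_drift(kappa_draws)
    T1 = np.atleast_2d(kappa_draws).shape[1] - 1
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5501]))
    return delta + sigma / math.sqrt(T1) * rng.standard_normal(delta.shape)


def project_year_effects(delta: np.ndarray, sigma: np.ndarray,
                         horizon_years: Sequence[int], seed: int = 0,
                         base_year: int = 2018,
                         kappa_base: float | np.ndarray = 0.0) -> np.ndarray:
    """Random-walk-with-drift kappa paths over the horizon, per draw.

    kappa_{base+h} = kappa_base + h*delta + sum of h Normal(0, sigma^2)
    innovations; reproducible given ``seed``.  Returns (n_draws, H).
    """
    horizon_years = sorted(int(y) for y in horizon_years)
    if len(horizon_years) == 0:
        return np.zeros((len(np.atleast_1d(delta)), 0))
    if horizon_years[0] <= base_year:
        raise SchemaError(
            f"projection horizon must start after the baseline year "
            f"{base_year}; got {horizon_years[0]}"
        )
    if horizon_years != list(range(horizon_years[0],
                                   horizon_years[0] + len(horizon_years))):
        raise SchemaError("projection horizon must be consecutive years")
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    n_draws, H = delta.shape[0], len(horizon_years)
    gap = horizon_years[0] - base_year          # usually 1
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4127]))
    z = rng.standard_normal((n_draws, H + gap - 1))
    innov = sigma[:, None] * z
    steps = delta[:, None] + innov
    paths = np.cumsum(steps, axis=1) + np.atleast_1d(kappa_base)[:, None]
    return paths[:, gap - 1:]


def build_horizon_frame(design: DesignInfo, years: Sequence[int],
                        exposures: pd.DataFrame | None = None,
                        base_exposure_year: int | None = None) -> pd.DataFrame:
    """Stratum-by-year frame for the horizon with exposures attached.

    Default exposure policy: hold the baseline (last fitted) year's
    exposures constant over the horizon; alternatively join a supplied
    exposure frame with the usual stratum key columns.
    """
    base_exposure_year = base_exposure_year or design.spec.base_year
    key_cols = ["cause", "sex", "age_group", "region", "deprivation"]
    base = design.table_index.copy()
    base["exposure"] = design.exposure
    base = base[base["year"] == base_exposure_year].drop(columns="year")
    rows = []
    for year in sorted(int(y) for y in years):
        f = base.copy()
        f["year"] = year
        rows.append(f)
    frame = pd.concat(rows, ignore_index=True)
    if exposures is not None:
        frame = frame.drop(columns="exposure").merge(
            exposures[key_cols + ["year", "exposure"]],
            on=key_cols + ["year"], how="left")
        if frame["exposure"].isna().any():
            miss = frame[frame["exposure"].isna()].iloc[0]
            raise SchemaError(f"horizon exposure missing for {dict(miss)}")
    return frame[key_cols[:3] + ["year"] + key_cols[3:] + ["exposure"]]


def _static_design(design: DesignInfo, frame: pd.DataFrame,
                   covariates: CovariateSeries
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Design columns for the year-free part of eta on a horizon frame.

    Returns (Z, mask) where mask selects the retained columns of theta.
    The year main effect is replaced by the projected kappa path, and
    interactions involving year contribute zero at/after the anchor year
    (their contrast is zero there), so both are dropped.
    """
    spec = design.spec
    n = len(frame)
    ages = list(design.ages)
    quintiles = list(design.quintiles)
    regions = list(design.regions)
    idx = {
        "age": frame["age_group"].map({a: i for i, a in enumerate(ages)}),
        "deprivation": frame["deprivation"].map(
            {q: i for i, q in enumerate(quintiles)}),
        "region": frame["region"].map({r: i for i, r in enumerate(regions)}),
    }
    for eff, series in idx.items():
        if series.isna().any():
            raise SchemaError(f"horizon frame has {eff} levels unseen in fit")
    cat = {eff: _contrast_matrix(len(lv))[idx[eff].to_numpy(int)]
           for eff, lv in (("age", ages), ("deprivation", quintiles),
                           ("region", regions))}

    ns_map = covariates.ns_lookup()
    aad_map = covariates.aad_lookup()

    def covariate_column(which: str) -> np.ndarray:
        vals = np.empty(n)
        for i, row in enumerate(frame.itertuples(index=False)):
            key = ((row.region, row.sex, int(row.year)) if which == "aad"
                   else (row.age_group, row.sex, int(row.year)))
            if key not in (aad_map if which == "aad" else ns_map):
                raise SchemaError(
                    f"horizon {which.upper()} covariate missing for {key}")
            vals[i] = (aad_map if which == "aad" else ns_map)[key]
        return vals

    cols: list[np.ndarray] = []
    mask = np.zeros(design.n_params, dtype=bool)
    for name, sl in design.blocks.items():
        if name == "year" or ":year" in name or name.endswith(":year") \
                or "year:" in name:
            continue
        if name == "intercept":
            cols.append(np.ones((n, 1)))
        elif name in ("age", "deprivation", "region"):
            cols.append(cat[name])
        elif name == "aad":
            cols.append((covariate_column("aad")
                         - design.aad_center)[:, None])
        elif name == "ns":
            cols.append((covariate_column("ns") - design.ns_center)[:, None])
        elif name == "region:deprivation":
            Ma, Mb = cat["region"], cat["deprivation"]
            cols.append((Ma[:, :, None] * Mb[:, None, :]).reshape(n, -1))
        else:                                  # pragma: no cover
            raise SchemaError(f"cannot project effect block {name!r}")
        mask[sl] = True
    return np.hstack(cols), mask


def project_rates(draws: PosteriorDraws, kappa_paths: np.ndarray,
                  covariates: CovariateSeries,
                  exposures: pd.DataFrame | None = None,
                  horizon_years: Sequence[int] | None = None,
                  seed: int = 0, fresh_heterogeneity: bool = True,
                  scenario: str = "baseline") -> ProjectionResult:
    """Posterior rate draws over the horizon with frozen non-year effects.

    ``kappa_paths`` is (n_draws, H) from :func:`project_year_effects`; the
    horizon defaults to consecutive years after the baseline matching its
    width.  Future cells get fresh eps ~ Normal(0, sigma_eps^2) per draw
    when ``fresh_heterogeneity`` (the predictive default).
    """
    design = draws.design
    H = kappa_paths.shape[1]
    if horizon_years is None:
        horizon_years = range(design.spec.base_year + 1,
                              design.spec.base_year + 1 + H)
    horizon_years = sorted(int(y) for y in horizon_years)
    if len(horizon_years) != H:
        raise SchemaError("kappa paths and horizon length differ")
    if kappa_paths.shape[0] != draws.n_draws:
        raise SchemaError("kappa paths and posterior draw counts differ")

    frame = build_horizon_frame(design, horizon_years, exposures)
    Z, mask = _static_design(design, frame, covariates)
    eta = draws.theta[:, mask] @ Z.T            # (n_draws, n_rows)
    year_idx = frame["year"].map(
        {y: i for i, y in enumerate(horizon_years)}).to_numpy(int)
    eta += kappa_paths[:, year_idx]
    if fresh_heterogeneity and design.spec.overdispersion:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9241]))
        eta += (draws.sigma_eps[:, None]
                * rng.standard_normal(eta.shape))
    rates = np.exp(eta)
    spec_hash = hashlib.sha1(repr(design.spec).encode()).hexdigest()[:12]
    return ProjectionResult(frame=frame, rate_draws=rates, scenario=scenario,
                            seed=int(seed), spec_hash=spec_hash)


def fitted_rates(draws: PosteriorDraws,
                 include_heterogeneity: bool = True) -> ProjectionResult:
    """In-sample rate draws on the fit grid (for ASMR and ratio work)."""
    design = draws.design
    eta = draws.theta @ design.X.T
    if include_heterogeneity and design.spec.overdispersion:
        eta = eta + draws.epsilon
    frame = design.table_index.copy()
    frame["exposure"] = design.exposure
    return ProjectionResult(frame=frame, rate_draws=np.exp(eta),
                            scenario="fitted", seed=draws.seed)


def expected_deaths(result: ProjectionResult,
                    exposures: pd.DataFrame | None = None,
                    predictive_poisson: bool = False,
                    seed: int = 0) -> np.ndarray:
    """Per-draw expected death counts E*m, optionally with Poisson noise.

    Returns (n_draws, n_rows) aligned with ``result.frame``; additive over
    strata per draw.  The optional Poisson layer yields predictive counts
    and is flagged by the argument, never applied silently.
    """
    if exposures is None:
        E = result.frame["exposure"].to_numpy(float)
    else:
        E = np.asarray(exposures, dtype=float)
    if np.any(E <= 0):
        raise SchemaError("exposures must be positive")
    mu = result.rate_draws * E[None, :]
    if predictive_poisson:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6011]))
        return rng.poisson(mu).astype(float)
    return mu
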