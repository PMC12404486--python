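"""Covariate preparation: non-smoker prevalence smoothing and AAD handling.

Non-smoker (NS) prevalence enters the mortality model as a smoking-exposure
proxy.  Observed survey prevalences are noisy, so a simple GLM of prevalence
on calendar year is fitted per (age band, sex) — binomial with logit link by
default, Gaussian-identity available for sensitivity — and the fitted series
is what the model consumes, optionally lagged to respect smoking latency.

Average age-at-diagnosis (AAD) enters as a (region, year, sex) series in
years of age; diagnosis-delay scenarios shift it additively by d/12 years
from a chosen year onward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import SchemaError
from .synthetic import CovariateSeries

__all__ = ["NSTrendFit", "fit_ns_trend", "lag_series", "shift_aad"]


@dataclass
class NSTrendFit:
    """Per-(age band, sex) GLM trend fit of NS prevalence on year."""

    family: str
    params: dict[tuple[str, str], tuple[float, float]]  # (intercept, slope)
    stderr: dict[tuple[str, str], tuple[float, float]]
    deviance: dict[tuple[str, str], float]
    year_range: tuple[int, int]
    fitted: pd.DataFrame = field(repr=False)  # age_group, sex, year, prevalence

    def predict(self, age_group: str, sex: str,
                years: Sequence[int]) -> pd.DataFrame:
        """Fitted prevalence for any years; extrapolation is flagged."""
        b0, b1 = self.params[(age_group, sex)]
        years = np.asarray(list(years), dtype=int)
        eta = b0 + b1 * years
        if self.family == "binomial_logit":
            p = 1.0 / (1.0 + np.exp(-eta))
        else:
            p = np.clip(eta, 0.0, 1.0)
        lo, hi = self.year_range
        return pd.DataFrame({
            "age_group": age_group, "sex": sex, "year": years,
            "prevalence": p,
            "extrapolated": (years < lo) | (years > hi),
        })


def fit_ns_trend(observed: pd.DataFrame,
                 family: str = "binomial_logit") -> NSTrendFit:
    """Fit a GLM trend of NS prevalence on year, per (age band, sex).

    ``observed`` needs columns age_group, sex, year, prevalence and
    optionally ``denominator`` (survey sample size; used as binomial
    weights when present).  At least three distinct years per series are
    required.
    """
    if family not in ("binomial_logit", "gaussian_identity"):
        raise SchemaError(f"unknown GLM family {family!r}")
    p = observed["prevalence"]
    if ((p < 0) | (p > 1)).any():
        raise SchemaError("observed prevalence outside [0, 1]")
    params, stderr, deviance, fitted_parts = {}, {}, {}, []
    for (age, sex), grp in observed.groupby(["age_group", "sex"], sort=False):
        years = grp["year"].to_numpy(int)
        if len(np.unique(years)) < 3:
            raise SchemaError(
                f"need >= 3 distinct years to fit NS trend for "
                f"({age}, {sex}); got {len(np.unique(years))}"
            )
        exog = sm.add_constant(years.astype(float))
        if family == "binomial_logit":
            fam = sm.families.Binomial()
            weights = (grp["denominator"].to_numpy(float)
                       if "denominator" in grp else np.ones(len(grp)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(grp["prevalence"].to_numpy(float), exog,
                             family=fam, var_weights=weights).fit()
        else:
            res = sm.OLS(grp["prevalence"].to_numpy(float), exog).fit()
        params[(age, sex)] = (float(res.params[0]), float(res.params[1]))
        stderr[(age, sex)] = (float(res.bse[0]), float(res.bse[1]))
        deviance[(age, sex)] = float(res.deviance
                                     if family == "binomial_logit"
                                     else res.ssr)
        fitted_parts.append(pd.DataFrame({
            "age_group": age, "sex": sex, "year": years,
            "prevalence": np.asarray(res.fittedvalues, dtype=float),
        }))
    yr = observed["year"]
    return NSTrendFit(family=family, params=params, stderr=stderr,
                      deviance=deviance,
                      year_range=(int(yr.min()), int(yr.max())),
                      fitted=pd.concat(fitted_parts, ignore_index=True))


def lag_series(fit: NSTrendFit, lag_years: int,
               model_years: Sequence[int] | None = None) -> pd.DataFrame:
    """NS prevalence series where the value at year t is the fit at t - lag.

    A pure reindexing of fitted values; lag 0 is the identity.  Years whose
    lagged counterpart predates the observed window raise an error (the GLM
    is not extrapolated backwards).
    """
    if lag_years < 0:
        raise SchemaError("lag must be >= 0")
    if model_years is None:
        lo, hi = fit.year_range
        model_years = range(lo + lag_years, hi + 1)
    model_years = sorted(int(y) for y in model_years)
    first_needed = model_years[0] - lag_years
    if first_needed < fit.year_range[0]:
        raise SchemaError(
            f"insufficient NS history: model year {model_years[0]} needs "
            f"fitted year {first_needed}, first available is "
            f"{fit.year_range[0]}"
        )
    parts = []
    for age, sex in fit.params:
        lagged = fit.predict(age, sex, [y - lag_years for y in model_years])
        lagged["year"] = model_years
        parts.append(lagged.drop(columns="extrapolated"))
    return pd.concat(parts, ignore_index=True)


def shift_aad(series: pd.DataFrame, delay_months: float,
              from_year: int) -> pd.DataFrame:
    """Add a diagnosis delay of ``delay_months``/12 years to AAD.

    Values for ``year >= from_year`` are shifted; earlier years untouched.
    Shifts are additive and order-independent.
    """
    if delay_months < 0:
        raise SchemaError("diagnosis delay must be >= 0 months")
    out = series.copy()
    mask = out["year"] >= from_year
    out.loc[mask, "aad_years"] = out.loc[mask, "aad_years"] + delay_months / 12.0
    return out


def shift_covariates(covariates: CovariateSeries, delay_months: float,
                     from_year: int) -> CovariateSeries:
    """Covariate bundle with the AAD series delay-shifted."""
    shifted = shift_aad(covariates.aad, delay_months, from_year)
    return CovariateSeries(covariates.ns.copy(), shifted,
                           (covariates.aad_band[0],
                      covariates.aad_band[1] + delay_months / 12.0))
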