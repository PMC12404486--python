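"""Poisson-lognormal Bayesian hierarchical mortality model.

Death counts D in stratum i follow

    D_i ~ Poisson(E_i * exp(eta_i + eps_i)),    eps_i ~ Normal(0, sigma_eps^2)

where E_i is person-years exposure and the log-rate eta_i is additive in an
intercept, sum-to-zero categorical effects for age band, deprivation
quintile and region, a year effect kappa_t anchored at the baseline (last
fitted) year, centred continuous covariates for average age-at-diagnosis
(AAD) and non-smoker (NS) prevalence, and optional two-way interactions.
The per-cell lognormal term eps captures heterogeneity beyond the Poisson
variance.

Priors are weakly informative: Normal(0, prior_sd^2) on all fixed effects
(default prior_sd = 10 on the log scale) and half-Normal on sigma_eps.

Posterior sampling is adaptive Metropolis-within-Gibbs: a joint random-walk
block for the fixed effects, preconditioned by the covariance of a Poisson
GLM fit to the same design; vectorised single-site updates for the cell
effects eps; and a log-scale update for sigma_eps.  Proposal scales adapt
during burn-in (Robbins-Monro toward canonical acceptance rates) and are
frozen afterwards, so the retained chain is a valid Markov chain.  Model
comparison uses the conditional Deviance Information Criterion with the
cell effects counted among the likelihood's parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_io import REGIONS, MortalityTable, SchemaError, age_groups_for
from .synthetic import CovariateSeries

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "ParamSet",
    "DesignInfo",
    "PosteriorDraws",
    "build_design",
    "linear_predictor",
    "log_likelihood",
    "sample_posterior",
    "compute_dic",
    "select_model",
]

MAIN_EFFECTS = ("age", "year", "deprivation", "region", "aad", "ns")
SUPPORTED_INTERACTIONS = (
    ("age", "year"), ("deprivation", "year"), ("region", "deprivation"),
)


@dataclass(frozen=True)
class ModelSpec:
    """Declared structure of one cause/sex hierarchical model."""

    cause: str
    sex: str
    main_effects: tuple[str, ...] = MAIN_EFFECTS
    interactions: tuple[tuple[str, str], ...] = ()
    prior_sd: float = 10.0
    prior_sd_overrides: tuple[tuple[str, float], ...] = ()
    sigma_eps_scale: float = 1.0
    overdispersion: bool = True
    base_year: int = 2018

    def __post_init__(self) -> None:
        unknown = set(self.main_effects) - set(MAIN_EFFECTS)
        if unknown:
            raise SchemaError(f"unknown main effects {sorted(unknown)}")
        if self.cause == "BC" and "aad" in self.main_effects:
            raise SchemaError(
                "AAD is excluded from breast-cancer models (no regional "
                "variability to inform it)"
            )
        for pair in self.interactions:
            if tuple(pair) not in SUPPORTED_INTERACTIONS:
                raise SchemaError(f"unsupported interaction {pair}")
            if not set(pair) <= set(self.main_effects):
                raise SchemaError(
                    f"interaction {pair} requires both main effects"
                )

    @property
    def effect_prior_sd(self) -> dict[str, float]:
        out = {e: self.prior_sd for e in MAIN_EFFECTS}
        out["intercept"] = self.prior_sd
        for pair in self.interactions:
            out[f"{pair[0]}:{pair[1]}"] = self.prior_sd
        out.update(dict(self.prior_sd_overrides))
        return out


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run settings; ``iterations`` counts per-chain sweeps incl. burn-in."""

    chains: int = 4
    iterations: int = 5000
    burn_in: int = 2500
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise SchemaError("burn_in must be < iterations")


#: desk-scale settings for the tiny fixture
TINY_MCMC = McmcConfig(chains=2, iterations=2000, burn_in=1000, thin=2)


@dataclass
class ParamSet:
    """One full parameter vector on the interpretable scale.

    Categorical effects are full-length (sum-to-zero; kappa anchored at the
    base year); interaction blocks are full matrices keyed by level pairs.
    """

    intercept: float
    age: dict[str, float]
    kappa: dict[int, float]
    gamma: dict[int, float]
    rho: dict[str, float]
    beta_aad: float
    beta_ns: float
    interactions: dict[tuple[str, str], pd.DataFrame] = field(
        default_factory=dict)
    aad_center: float = 0.0
    ns_center: float = 0.0
    sigma_eps: float = 0.0


def _contrast_matrix(n_levels: int, anchored: bool = False,
                     anchor_index: int = -1) -> np.ndarray:
    """Map free parameters to full effect vectors.

    Sum-to-zero coding: the last level carries minus the sum of the free
    ones.  Anchored coding (for the year effect): the anchor level is 0.
    """
    k = n_levels
    C = np.zeros((k, max(k - 1, 0)))
    if k <= 1:
        return C
    if anchored:
        free = [i for i in range(k) if i != anchor_index % k]
        for j, lev in enumerate(free):
            C[lev, j] = 1.0
    else:
        C[:k - 1] = np.eye(k - 1)
        C[k - 1] = -1.0
    return C


@dataclass
class DesignInfo:
    """Design matrix and bookkeeping tying free parameters to the grid."""

    spec: ModelSpec
    X: np.ndarray                      # (n, p) including intercept column
    col_names: list[str]
    blocks: dict[str, slice]           # effect name -> column slice
    ages: tuple[str, ...]
    years: tuple[int, ...]
    quintiles: tuple[int, ...]
    regions: tuple[str, ...]
    aad_center: float
    ns_center: float
    deaths: np.ndarray
    exposure: np.ndarray
    table_index: pd.DataFrame          # stratum key columns, row-aligned to X

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def prior_sd_vector(self) -> np.ndarray:
        sds = self.spec.effect_prior_sd
        out = np.empty(self.n_params)
        for name, sl in self.blocks.items():
            out[sl] = sds.get(name, self.spec.prior_sd)
        return out

    def expand(self, theta: np.ndarray, sigma_eps: float = 0.0) -> ParamSet:
        """Free parameter vector -> interpretable full-length ParamSet."""
        b = self.blocks
        get = lambda name: theta[b[name]] if name in b else np.zeros(0)

        def full(name, levels, anchored=False, anchor=None):
            if name not in b:
                return dict.fromkeys(levels, 0.0)
            C = _contrast_matrix(len(levels), anchored,
                                 levels.index(anchor) if anchored else -1)
            return dict(zip(levels, C @ get(name)))

        ages = list(self.ages)
        years = list(self.years)
        inter = {}
        for pair in self.spec.interactions:
            name = f"{pair[0]}:{pair[1]}"
            if name not in b:
                continue
            la = self._levels(pair[0])
            lb = self._levels(pair[1])
            Ca = self._contrast_for(pair[0])
            Cb = self._contrast_for(pair[1])
            Theta = get(name).reshape(Ca.shape[1], Cb.shape[1])
            inter[pair] = pd.DataFrame(Ca @ Theta @ Cb.T, index=la, columns=lb)
        return ParamSet(
            intercept=float(theta[b["intercept"]][0]),
            age=full("age", ages),
            kappa=full("year", years, anchored=True,
                       anchor=self.spec.base_year),
            gamma=full("deprivation", list(self.quintiles)),
            rho=full("region", list(self.regions)),
            beta_aad=float(get("aad")[0]) if "aad" in b else 0.0,
            beta_ns=float(get("ns")[0]) if "ns" in b else 0.0,
            interactions=inter,
            aad_center=self.aad_center,
            ns_center=self.ns_center,
            sigma_eps=float(sigma_eps),
        )

    def _levels(self, effect: str):
        return {"age": list(self.ages), "year": list(self.years),
                "deprivation": list(self.quintiles),
                "region": list(self.regions)}[effect]

    def _contrast_for(self, effect: str) -> np.ndarray:
        levels = self._levels(effect)
        if effect == "year":
            return _contrast_matrix(len(levels), True,
                                    levels.index(self.spec.base_year))
        return _contrast_matrix(len(levels))


def build_design(spec: ModelSpec, table: MortalityTable,
                 covariates: CovariateSeries) -> DesignInfo:
    """Construct the dense design for a table under a model spec."""
    df = table.sorted().data
    if len(df) == 0:
        raise SchemaError("cannot build a design on an empty table")
    canonical_ages = age_groups_for(spec.cause)
    ages = tuple(a for a in canonical_ages if a in set(df["age_group"]))
    years = tuple(sorted(df["year"].unique()))
    quintiles = tuple(sorted(df["deprivation"].unique()))
    regions = tuple(r for r in REGIONS if r in set(df["region"]))
    if "year" in spec.main_effects and spec.base_year not in years:
        raise SchemaError(
            f"baseline year {spec.base_year} absent from the table"
        )

    n = len(df)
    idx = {
        "age": df["age_group"].map({a: i for i, a in enumerate(ages)}
                                   ).to_numpy(int),
        "year": df["year"].map({y: i for i, y in enumerate(years)}
                               ).to_numpy(int),
        "deprivation": df["deprivation"].map(
            {q: i for i, q in enumerate(quintiles)}).to_numpy(int),
        "region": df["region"].map({r: i for i, r in enumerate(regions)}
                                   ).to_numpy(int),
    }
    n_levels = {"age": len(ages), "year": len(years),
                "deprivation": len(quintiles), "region": len(regions)}

    ns_map = covariates.ns_lookup()
    aad_map = covariates.aad_lookup()

    def covariate_column(which: str) -> np.ndarray:
        vals = np.empty(n)
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                if which == "aad":
                    vals[i] = aad_map[(row.region, row.sex, int(row.year))]
                else:
                    vals[i] = ns_map[(row.age_group, row.sex, int(row.year))]
            except KeyError as exc:
                raise SchemaError(
                    f"{which.upper()} covariate missing for cell {exc.args[0]}"
                ) from exc
        return vals

    cols: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    blocks: dict[str, slice] = {"intercept": slice(0, 1)}
    pos = 1

    def add_block(name: str, mat: np.ndarray, labels: list[str]) -> None:
        nonlocal pos
        if mat.shape[1] == 0:
            return
        cols.append(mat)
        names.extend(labels)
        blocks[name] = slice(pos, pos + mat.shape[1])
        pos += mat.shape[1]

    cat_cols: dict[str, np.ndarray] = {}
    for eff in ("age", "year", "deprivation", "region"):
        k = n_levels[eff]
        anchored = eff == "year"
        anchor = list(years).index(spec.base_year) if anchored else -1
        C = _contrast_matrix(k, anchored, anchor)
        mat = C[idx[eff]]                      # (n, k-1)
        cat_cols[eff] = mat
        if eff in spec.main_effects:
            levels = {"age": ages, "year": years,
                      "deprivation": quintiles, "region": regions}[eff]
            if anchored:
                labs = [f"kappa[{y}]" for y in years if y != spec.base_year]
            else:
                labs = [f"{eff}[{lv}]" for lv in levels[:-1]]
            add_block(eff, mat, labs)

    aad_center = ns_center = 0.0
    if "aad" in spec.main_effects:
        aad_vals = covariate_column("aad")
        aad_center = float(aad_vals.mean())
        add_block("aad", (aad_vals - aad_center)[:, None], ["beta_aad"])
    if "ns" in spec.main_effects:
        ns_vals = covariate_column("ns")
        ns_center = float(ns_vals.mean())
        add_block("ns", (ns_vals - ns_center)[:, None], ["beta_ns"])

    for pair in spec.interactions:
        a, bname = pair
        Ma, Mb = cat_cols[a], cat_cols[bname]
        if Ma.shape[1] == 0 or Mb.shape[1] == 0:
            continue
        prod = (Ma[:, :, None] * Mb[:, None, :]).reshape(n, -1)
        labs = [f"{a}:{bname}[{i},{j}]"
                for i in range(Ma.shape[1]) for j in range(Mb.shape[1])]
        add_block(f"{a}:{bname}", prod, labs)

    X = np.hstack(cols)
    return DesignInfo(
        spec=spec, X=X, col_names=names, blocks=blocks, ages=ages,
        years=years, quintiles=quintiles, regions=regions,
        aad_center=aad_center, ns_center=ns_center,
        deaths=df["deaths"].to_numpy(float),
        exposure=df["exposure"].to_numpy(float),
        table_index=df[["cause", "sex", "age_group", "year", "region",
                        "deprivation"]].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Likelihood

def linear_predictor(spec: ModelSpec, params: ParamSet, key,
                     covariates: CovariateSeries) -> float:
    """Log rate eta for a single stratum under one parameter vector."""
    eta = params.intercept
    if "age" in spec.main_effects:
        eta += params.age[key.age_group]
    if "year" in spec.main_effects:
        eta += params.kappa[key.year]
    if "deprivation" in spec.main_effects:
        eta += params.gamma[key.deprivation]
    if "region" in spec.main_effects:
        eta += params.rho[key.region]
    if "aad" in spec.main_effects:
        try:
            a = covariates.aad_lookup()[(key.region, key.sex, key.year)]
        except KeyError:
            raise SchemaError(f"AAD covariate missing for {key}")
        eta += params.beta_aad * (a - params.aad_center)
    if "ns" in spec.main_effects:
        try:
            p = covariates.ns_lookup()[(key.age_group, key.sex, key.year)]
        except KeyError:
            raise SchemaError(f"NS covariate missing for {key}")
        eta += params.beta_ns * (p - params.ns_center)
    level = {"age": key.age_group, "year": key.year,
             "deprivation": key.deprivation, "region": key.region}
    for pair, mat in params.interactions.items():
        eta += float(mat.loc[level[pair[0]], level[pair[1]]])
    return float(eta)


def _poisson_loglik(deaths: np.ndarray, mu: np.ndarray) -> float:
    """Sum of Poisson log-pmfs, computed in log space."""
    if np.any(np.isnan(mu)):
        raise FloatingPointError("NaN Poisson mean")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = deaths * np.log(mu)
    term = np.where((deaths == 0) & (mu == 0), 0.0, term)
    return float(np.sum(term - mu - gammaln(deaths + 1.0)))


def log_likelihood(spec: ModelSpec, params: ParamSet, table: MortalityTable,
                   covariates: CovariateSeries,
                   epsilon: np.ndarray | None = None) -> float:
    """Poisson log-likelihood of a table under one parameter vector.

    ``epsilon`` optionally supplies the per-cell heterogeneity term, aligned
    to the table's canonical row order; omitted means eps = 0.
    """
    from .data_io import StratumKey

    df = table.sorted().data
    eta = np.array([
        linear_predictor(spec, params,
                         StratumKey(r.cause, r.sex, r.age_group, int(r.year),
                                    r.region, int(r.deprivation)), covariates)
        for r in df.itertuples(index=False)
    ])
    if epsilon is not None:
        eta = eta + np.asarray(epsilon, dtype=float)
    mu = df["exposure"].to_numpy(float) * np.exp(eta)
    return _poisson_loglik(df["deaths"].to_numpy(float), mu)


# ---------------------------------------------------------------------------
# Posterior sampling

@dataclass
class PosteriorDraws:
    """Retained MCMC draws plus the design they were sampled on."""

    design: DesignInfo
    theta: np.ndarray                 # (n_draws, p)
    sigma_eps: np.ndarray             # (n_draws,)
    epsilon: np.ndarray               # (n_draws, n_cells), zeros if disabled
    chain_id: np.ndarray              # (n_draws,)
    diagnostics: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    def param_set(self, i: int) -> ParamSet:
        return self.design.expand(self.theta[i], self.sigma_eps[i])

    def _block_draws(self, name: str, levels, anchored=False, anchor=None):
        if name not in self.design.blocks:
            return np.zeros((self.n_draws, len(levels)))
        C = (_contrast_matrix(len(levels), anchored, levels.index(anchor))
             if anchored else _contrast_matrix(len(levels)))
        return self.theta[:, self.design.blocks[name]] @ C.T

    def kappa_draws(self) -> np.ndarray:
        """(n_draws, n_years) year-effect paths, base year pinned at 0."""
        years = list(self.design.years)
        return self._block_draws("year", years, anchored=True,
                                 anchor=self.spec.base_year)

    def alpha_draws(self) -> np.ndarray:
        return self._block_draws("age", list(self.design.ages))

    def gamma_draws(self) -> np.ndarray:
        return self._block_draws("deprivation", list(self.design.quintiles))

    def rho_draws(self) -> np.ndarray:
        return self._block_draws("region", list(self.design.regions))

    def scalar_draws(self, name: str) -> np.ndarray:
        if name not in self.design.blocks:
            return np.zeros(self.n_draws)
        return self.theta[:, self.design.blocks[name]].ravel()

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        a = (1 - level) / 2
        qs = np.quantile(self.theta, [a, 1 - a], axis=0)
        return pd.DataFrame({
            "param": self.design.col_names,
            "mean": self.theta.mean(axis=0),
            "lo": qs[0], "hi": qs[1],
        })


def _glm_preconditioner(design: DesignInfo):
    """Poisson-GLM point fit and covariance used to precondition proposals."""
    import statsmodels.api as sm

    offset = np.log(design.exposure)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(design.deaths, design.X,
                         family=sm.families.Poisson(), offset=offset).fit()
        beta = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(cov))):
            raise ValueError("non-finite GLM fit")
    except Exception:
        # ridge fallback: crude rate intercept, unit-ish covariance
        beta = np.zeros(design.n_params)
        rate = max(design.deaths.sum(), 0.5) / design.exposure.sum()
        beta[0] = math.log(rate)
        cov = np.eye(design.n_params) * 0.01
    return beta, cov


def sample_posterior(spec: ModelSpec, table: MortalityTable,
                     covariates: CovariateSeries,
                     mcmc: McmcConfig = McmcConfig()) -> PosteriorDraws:
    """Sample the posterior by adaptive Metropolis-within-Gibbs.

    Reproducible given ``mcmc.seed``; raises on a rank-deficient design;
    warns (never errors) when the potential scale reduction factor exceeds
    1.05 for any fixed effect.
    """
    design = build_design(spec, table, covariates)
    X, D, E = design.X, design.deaths, design.exposure
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise SchemaError(
            "non-identifiable model: design matrix is rank deficient after "
            "constraints"
        )
    prior_sd = design.prior_sd_vector()
    free = prior_sd > 1e-12            # zero prior s.d. pins a coefficient
    prior_var = np.where(free, prior_sd, 1.0) ** 2

    beta0, cov = _glm_preconditioner(design)
    beta0 = np.where(free, beta0, 0.0)
    cov_f = cov[np.ix_(free, free)]
    cov_f = 0.5 * (cov_f + cov_f.T) + 1e-9 * np.eye(free.sum())
    L = np.linalg.cholesky(cov_f)

    n_keep = (mcmc.iterations - mcmc.burn_in) // mcmc.thin
    total = mcmc.chains * n_keep
    theta_out = np.empty((total, p))
    sig_out = np.empty(total)
    eps_out = np.zeros((total, n), dtype=np.float32)
    chain_out = np.empty(total, dtype=int)

    root = np.random.SeedSequence([int(mcmc.seed), 2218])
    chain_seeds = root.spawn(mcmc.chains)

    def log_prior_theta(th):
        return -0.5 * float(np.sum(th[free] ** 2 / prior_var[free]))

    pos = 0
    for c in range(mcmc.chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = beta0.copy()
        theta[free] += 0.1 * (L @ rng.standard_normal(free.sum()))
        eps = np.zeros(n)
        sigma = 0.05 if spec.overdispersion else 0.0

        eta_fix = X @ theta
        lam_fix = E * np.exp(eta_fix + eps)
        ll = float(np.sum(D * (eta_fix + eps)) - lam_fix.sum())
        lp = log_prior_theta(theta)

        log_s_theta = math.log(2.38 / math.sqrt(max(free.sum(), 1)))
        log_s_eps = math.log(0.5)
        log_s_sig = math.log(0.3)

        for it in range(mcmc.iterations):
            adapting = it < mcmc.burn_in
            # --- fixed-effect block ---
            step = np.zeros(p)
            step[free] = math.exp(log_s_theta) * (
                L @ rng.standard_normal(free.sum()))
            theta_prop = theta + step
            eta_prop = X @ theta_prop
            ll_prop = float(np.sum(D * (eta_prop + eps))
                            - np.sum(E * np.exp(eta_prop + eps)))
            lp_prop = log_prior_theta(theta_prop)
            log_a = (ll_prop + lp_prop) - (ll + lp)
            accept = math.log(rng.random()) < log_a
            if accept:
                theta, eta_fix, ll, lp = theta_prop, eta_prop, ll_prop, lp_prop
            if adapting:
                acc = min(1.0, math.exp(min(log_a, 0.0)))
                log_s_theta += (acc - 0.234) / math.sqrt(it + 1.0)

            # --- per-cell heterogeneity ---
            if spec.overdispersion:
                z = rng.standard_normal(n)
                eps_prop = eps + math.exp(log_s_eps) * z
                base = E * np.exp(eta_fix)
                d_ll = (D * (eps_prop - eps)
                        - base * (np.exp(eps_prop) - np.exp(eps)))
                d_pr = -(eps_prop ** 2 - eps ** 2) / (2.0 * sigma ** 2)
                log_u = np.log(rng.random(n))
                acc_mask = log_u < d_ll + d_pr
                eps = np.where(acc_mask, eps_prop, eps)
                if adapting:
                    rate = float(np.mean(np.exp(np.minimum(d_ll + d_pr, 0.0))))
                    log_s_eps += (rate - 0.44) / math.sqrt(it + 1.0)
                ll = float(np.sum(D * (eta_fix + eps))
                           - np.sum(E * np.exp(eta_fix + eps)))

                # --- sigma_eps, log-scale random walk ---
                sig_prop = sigma * math.exp(
                    math.exp(log_s_sig) * rng.standard_normal())
                sse = float(np.sum(eps ** 2))

                def sig_logpost(s):
                    return (-n * math.log(s) - sse / (2 * s * s)
                            - s * s / (2 * spec.sigma_eps_scale ** 2)
                            + math.log(s))          # Jacobian of log-scale RW

                log_a_s = sig_logpost(sig_prop) - sig_logpost(sigma)
                if math.log(rng.random()) < log_a_s:
                    sigma = sig_prop
                if adapting:
                    acc_s = min(1.0, math.exp(min(log_a_s, 0.0)))
                    log_s_sig += (acc_s - 0.44) / math.sqrt(it + 1.0)

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 \
                    and pos < (c + 1) * n_keep:
                theta_out[pos] = theta
                sig_out[pos] = sigma
                if spec.overdispersion:
                    eps_out[pos] = eps
                chain_out[pos] = c
                pos += 1

    theta_out, sig_out = theta_out[:pos], sig_out[:pos]
    eps_out, chain_out = eps_out[:pos], chain_out[:pos]

    diagnostics = _diagnose(theta_out, chain_out, design.col_names,
                            mcmc.chains)
    if diagnostics.get("max_rhat", 1.0) > 1.05:
        warnings.warn(
            f"potential scale reduction {diagnostics['max_rhat']:.3f} > 1.05 "
            f"for {diagnostics['worst_param']}; consider longer chains",
            stacklevel=2)
    return PosteriorDraws(design=design, theta=theta_out, sigma_eps=sig_out,
                          epsilon=eps_out, chain_id=chain_out,
                          diagnostics=diagnostics, seed=mcmc.seed)


def _diagnose(theta: np.ndarray, chain_id: np.ndarray,
              names: list[str], n_chains: int) -> dict:
    """Split-R-hat and bulk ESS per fixed effect (via arviz)."""
    if n_chains < 2 or theta.shape[0] < 4:
        return {"max_rhat": float("nan"), "worst_param": None, "ess": {}}
    import arviz as az

    per = theta.shape[0] // n_chains
    if per < 2:
        return {"max_rhat": float("nan"), "worst_param": None, "ess": {}}
    cube = theta[:n_chains * per].reshape(n_chains, per, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(az.convert_to_dataset(cube))["x"].values
        ess = az.ess(az.convert_to_dataset(cube))["x"].values
    worst = int(np.nanargmax(rhat))
    return {
        "rhat": dict(zip(names, rhat.tolist())),
        "ess": dict(zip(names, ess.tolist())),
        "max_rhat": float(np.nanmax(rhat)),
        "worst_param": names[worst],
    }


# ---------------------------------------------------------------------------
# DIC and selection

def compute_dic(draws: PosteriorDraws, spec: ModelSpec | None = None,
                table: MortalityTable | None = None,
                covariates: CovariateSeries | None = None) -> dict:
    """Conditional DIC: cell effects eps count among likelihood parameters.

    DIC = mean deviance + p_D with p_D = mean deviance - deviance at the
    posterior mean of (theta, eps).  Needs >= 100 retained draws for a
    stable p_D.
    """
    if draws.n_draws < 100:
        raise SchemaError(
            f"DIC needs >= 100 retained draws for a stable p_D; "
            f"got {draws.n_draws}"
        )
    design = draws.design
    X, D, E = design.X, design.deaths, design.exposure
    dev = np.empty(draws.n_draws)
    for i in range(draws.n_draws):
        mu = E * np.exp(X @ draws.theta[i] + draws.epsilon[i])
        dev[i] = -2.0 * _poisson_loglik(D, mu)
    mean_dev = float(dev.mean())
    mu_bar = E * np.exp(X @ draws.theta.mean(axis=0)
                        + draws.epsilon.mean(axis=0))
    dev_at_mean = -2.0 * _poisson_loglik(D, mu_bar)
    p_d = mean_dev - dev_at_mean
    return {"dic": mean_dev + p_d, "p_d": p_d, "mean_deviance": mean_dev}


def select_model(candidates: Sequence[ModelSpec], table: MortalityTable,
                 covariates: CovariateSeries,
                 mcmc: McmcConfig = McmcConfig()) -> dict:
    """Greedy DIC-based selection over an ordered candidate list.

    Returns the argmin-DIC spec with the full trace; ties break toward
    fewer parameters.  Non-identifiable candidates are skipped with a
    warning.  Selection is DIC-only by design.
    """
    if len(candidates) == 0:
        raise SchemaError("need at least one candidate model")
    trace = []
    for k, cand in enumerate(candidates):
        sub_mcmc = replace(mcmc, seed=mcmc.seed)
        try:
            draws = sample_posterior(cand, table, covariates, sub_mcmc)
        except SchemaError as exc:
            warnings.warn(f"candidate {k} skipped: {exc}", stacklevel=2)
            continue
        dic = compute_dic(draws)
        trace.append({"candidate": k, "spec": cand,
                      "n_params": draws.design.n_params, **dic})
    if not trace:
        raise SchemaError("no evaluable candidate model")
    best = min(trace, key=lambda t: (round(t["dic"], 6), t["n_params"]))
    return {"best": best["spec"], "best_dic": best["dic"], "trace": trace,
            "criterion": "conditional DIC (DIC-only selection)"}
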