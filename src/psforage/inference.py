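"""Statistical models linking scrounging to individual and social predictors.

Four analyses operate on the classified event tables and networks:

* :func:`fit_binomial_glmm` — per-bird scrounge vs. solve counts against
  individual covariates (age, sex, first-contact time, latency to learn,
  exploration, total rewarded visits as control) with a random intercept
  for replicate;
* :func:`repeatability` — intraclass correlation of the binary
  scrounge/solve outcome across a bird's rewarded events,
  R = V_ind / (V_ind + V_e), with V_e = pi^2 / 3 on the latent (logit)
  scale and a parametric-bootstrap confidence interval;
* :func:`network_permutation_test` — significance of a sociability metric
  (strength, degree, betweenness, average group size) by refitting the
  model along a stratified data-stream permutation chain, with the
  95%-range criterion plus an empirical p-value;
* :func:`subpop_regression` — replicate-level OLS of the proportion of
  scrounger-labelled birds on subpopulation size, controlling for year.

Covariates are standardized (zero mean, unit variance) before fitting so
coefficients are comparable across metrics and simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .gatherings import GroupByIndividual
from .glmm import MixedFit, fit_glm_binomial, fit_glmm_binomial
from .network import gbi_metric, make_swapper

LATENT_RESIDUAL_VAR = np.pi**2 / 3  # logistic link-scale residual variance

__all__ = [
    "GLMMFit",
    "RepeatabilityEstimate",
    "PermutationTestResult",
    "SubpopRegressionResult",
    "fit_binomial_glmm",
    "repeatability",
    "network_permutation_test",
    "subpop_regression",
    "simulate_glmm_dataset",
    "simulate_event_level",
    "LATENT_RESIDUAL_VAR",
]


def build_design(
    data: pd.DataFrame, fixed_effects: list[str], standardize: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept; categoricals dummy-coded, all columns
    standardized to zero mean / unit variance (the reporting convention
    for the scrounging models)."""
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["intercept"]
    for name in fixed_effects:
        col = data[name]
        if col.isna().any():
            raise ValueError(f"covariate {name!r} has missing values")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(float))
                names.append(dc)
        else:
            cols.append(col.to_numpy(float))
            names.append(name)
    X = np.column_stack(cols)
    if standardize:
        for j in range(1, X.shape[1]):
            sd = X[:, j].std()
            if sd > 0:
                X[:, j] = (X[:, j] - X[:, j].mean()) / sd
    return X, names


@dataclass
class GLMMFit:
    """Fitted scrounge/solve mixed model with a per-term summary table."""

    params: pd.DataFrame  # coef, se, z, p per term
    sigma2_group: float
    loglik: float
    n: int
    n_groups: int
    singular: bool
    method: str
    fit: MixedFit = field(repr=False)

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "coef"])


def fit_binomial_glmm(
    data: pd.DataFrame,
    fixed_effects: list[str],
    response: tuple[str, str] = ("n_scrounges", "n_solves"),
    group: str = "replicate",
    interactions: list[tuple[str, str]] | None = None,
    n_quad: int = 15,
) -> GLMMFit:
    """Fit scrounge vs. solve counts against covariates with a replicate
    random intercept.

    ``response`` names the (successes, failures) count columns: the model
    is binomial with m = scrounges + solves trials per bird. Optional
    ``interactions`` add products of two already-standardized columns
    (e.g. sociability x first-contact).
    """
    data = data.copy()
    groups_codes, _ = pd.factorize(data[group], sort=True)
    if groups_codes.max() + 1 < 2:
        warnings.warn(
            "fewer than 2 grouping levels; the random intercept is not "
            "identifiable and a plain GLM will be returned", RuntimeWarning,
        )
    y = data[response[0]].to_numpy(float)
    m = y + data[response[1]].to_numpy(float)
    if np.any(m <= 0):
        raise ValueError("every bird needs at least one rewarded visit")
    X, names = build_design(data, fixed_effects)
    if interactions:
        for a, b in interactions:
            ia, ib = names.index(a), names.index(b)
            X = np.column_stack([X, X[:, ia] * X[:, ib]])
            names.append(f"{a}:{b}")

    if groups_codes.max() + 1 < 2:
        glm = fit_glm_binomial(X, y, m)
        from scipy.stats import norm as _norm

        z = np.where(glm.se > 0, glm.beta / glm.se, np.nan)
        fit = MixedFit(
            beta=glm.beta, se=glm.se, zvalues=z,
            pvalues=2 * _norm.sf(np.abs(z)), sigma2=0.0, loglik=glm.loglik,
            n=len(y), n_groups=1, converged=glm.converged, singular=True,
            method="glm-fallback",
        )
    else:
        fit = fit_glmm_binomial(X, y, m, groups_codes, n_quad=n_quad)
    table = pd.DataFrame(
        {"coef": fit.beta, "se": fit.se, "z": fit.zvalues, "p": fit.pvalues},
        index=pd.Index(names, name="term"),
    )
    return GLMMFit(
        params=table, sigma2_group=fit.sigma2, loglik=fit.loglik, n=fit.n,
        n_groups=fit.n_groups, singular=fit.singular, method=fit.method,
        fit=fit,
    )


@dataclass
class RepeatabilityEstimate:
    """Intraclass correlation of tactic use, R = V_ind / (V_ind + V_e)."""

    R: float
    CI_low: float | None
    CI_high: float | None
    V_ind: float
    V_e: float
    scale: str
    n_birds: int
    n_events: int


def _aggregate_events(
    data: pd.DataFrame, bird: str, response: str, fixed: list[str]
):
    """Collapse event-level binary rows to binomial counts per
    bird x fixed-effect pattern (identical likelihood, much faster)."""
    keys = [bird] + list(fixed)
    g = data.groupby(keys, sort=True, observed=True)[response]
    agg = g.agg(["sum", "count"]).reset_index()
    return agg.rename(columns={"sum": "_y", "count": "_m"})


def repeatability(
    data: pd.DataFrame,
    bird: str = "bird_id",
    response: str = "is_scrounge",
    fixed: list[str] | None = None,
    scale: str = "latent",
    n_boot: int = 500,
    n_quad: int = 15,
    rng: np.random.Generator | None = None,
) -> RepeatabilityEstimate:
    """Repeatability (ICC) of the scrounge-vs-solve outcome across events.

    Every rewarded event contributes one binary row (scrounge = 1,
    solve = 0); ``fixed`` (e.g. date and replicate) enter as dummy-coded
    fixed effects and the bird identity as the random intercept. On the
    default latent scale the residual variance of the logit link is fixed
    at pi^2/3, so R = V_ind / (V_ind + pi^2/3). ``scale='original'``
    instead decomposes variance on the observation scale by Gauss-Hermite
    integration over the fitted intercept distribution. The confidence
    interval is a percentile parametric bootstrap (``n_boot`` refits;
    0 skips the interval).
    """
    fixed = list(fixed) if fixed else []
    n_events = len(data)
    birds = data[bird].unique()
    if len(birds) < 2:
        raise ValueError("repeatability is undefined with a single bird")

    agg = _aggregate_events(data, bird, response, fixed)
    y = agg["_y"].to_numpy(float)
    m = agg["_m"].to_numpy(float)
    X, _ = build_design(agg, fixed, standardize=False)
    codes, _ = pd.factorize(agg[bird], sort=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_glmm_binomial(X, y, m, codes, n_quad=n_quad)

    def to_R(mf: MixedFit) -> tuple[float, float, float]:
        v_ind = mf.sigma2
        if scale == "latent":
            v_e = LATENT_RESIDUAL_VAR
            return v_ind / (v_ind + v_e), v_ind, v_e
        if scale == "original":
            if v_ind <= 0:
                return 0.0, 0.0, 0.25
            from numpy.polynomial.hermite import hermgauss

            nodes, wts = hermgauss(31)
            eta_bar = float(np.average(X @ mf.beta, weights=m))
            u = np.sqrt(2 * v_ind) * nodes
            w = wts / np.sqrt(np.pi)
            p = expit(eta_bar + u)
            mean_p = float(np.sum(w * p))
            v_between = float(np.sum(w * (p - mean_p) ** 2))
            v_within = float(np.sum(w * p * (1 - p)))
            return v_between / (v_between + v_within), v_between, v_within
        raise ValueError(f"unknown scale {scale!r}")

    R, v_ind, v_e = to_R(fit)

    ci_low = ci_high = None
    if n_boot > 0:
        rng = np.random.default_rng() if rng is None else rng
        n_groups = codes.max() + 1
        eta_fix = X @ fit.beta
        sigma = np.sqrt(fit.sigma2)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            u = rng.normal(0.0, sigma, n_groups)
            yb = rng.binomial(m.astype(int), expit(eta_fix + u[codes]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                try:
                    fb = fit_glmm_binomial(X, yb, m, codes, n_quad=n_quad)
                    draws[b] = to_R(fb)[0]
                except Exception:
                    draws[b] = np.nan
        draws = draws[np.isfinite(draws)]
        if draws.size:
            ci_low = float(np.quantile(draws, 0.025))
            ci_high = float(np.quantile(draws, 0.975))
            ci_low, ci_high = min(ci_low, R), max(ci_high, R)

    return RepeatabilityEstimate(
        R=float(R), CI_low=ci_low, CI_high=ci_high, V_ind=float(v_ind),
        V_e=float(v_e), scale=scale, n_birds=len(birds), n_events=n_events,
    )


@dataclass
class PermutationTestResult:
    """Observed coefficient against its stratified permutation null."""

    metric: str
    observed: float
    null: np.ndarray
    n_perm: int
    significant: bool
    p_empirical: float
    null_q025: float
    null_q975: float
    n_swaps_total: int


def network_permutation_test(
    gbi: GroupByIndividual,
    metric: str,
    data: pd.DataFrame,
    fixed_effects: list[str],
    response: tuple[str, str] = ("n_scrounges", "n_solves"),
    group: str = "replicate",
    n_perm: int = 10_000,
    burn_in: int = 1_000,
    attempts_per_step: int | None = None,
    fitter: str = "auto",
    rng: np.random.Generator | None = None,
) -> PermutationTestResult:
    """Data-stream permutation test for one sociability metric.

    The observed coefficient comes from the model fitted on the real GBI.
    The chain then performs stratified checkerboard swaps (burn-in first,
    then ``attempts_per_step`` per recorded step); after each step the
    metric is recomputed from the permuted GBI and the model refitted,
    giving the null distribution of the coefficient. By default
    ``attempts_per_step`` is one tenth of the number of 1s in the GBI
    (at least 1): recorded samples must be separated by enough swap
    attempts to decorrelate, otherwise the serial chain understates the
    null spread and the range criterion over-rejects. Significance follows
    the 95%-range rule (observed outside the [2.5%, 97.5%] null
    quantiles); an empirical two-sided p-value
    (1 + #{|null - mean| >= |obs - mean|}) / (n_perm + 1) accompanies it.

    ``data`` is the per-bird covariate/count table indexed by bird id;
    only birds present in both the GBI and ``data`` enter the model.
    ``fitter`` is 'glm', 'glmm' or 'auto' (GLMM when >= 2 grouping
    levels — inside the chain the same fitter is reused).
    """
    rng = np.random.default_rng() if rng is None else rng
    obs_metric = gbi_metric(gbi, metric)
    if float(obs_metric.std()) == 0.0:
        raise ValueError(f"metric {metric!r} is constant across birds")

    common = [b for b in gbi.birds if b in data.index]
    if len(common) < 3:
        raise ValueError("too few birds shared between GBI and covariate table")
    sub = data.loc[common]
    y = sub[response[0]].to_numpy(float)
    m = y + sub[response[1]].to_numpy(float)
    X0, names = build_design(sub, fixed_effects)
    col_sel = np.array([gbi.birds.index(b) for b in common])

    if fitter == "auto":
        n_levels = sub[group].nunique() if group in sub else 1
        fitter = "glmm" if n_levels >= 2 else "glm"
    if fitter == "glmm":
        codes, _ = pd.factorize(sub[group], sort=True)

    def fit_coef(metric_values: np.ndarray) -> float:
        v = metric_values[col_sel]
        sd = v.std()
        v = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        X = np.column_stack([X0, v])
        if fitter == "glmm":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return float(fit_glmm_binomial(X, y, m, codes).beta[-1])
        return float(fit_glm_binomial(X, y, m, check_separation=False).beta[-1])

    observed = fit_coef(obs_metric.to_numpy(float))

    if attempts_per_step is None:
        attempts_per_step = max(1, int(np.ceil(gbi.matrix.sum() / 10)))
    work = gbi.copy()
    mat, attempt = make_swapper(work)
    work.matrix = mat
    n_swaps = 0
    for _ in range(burn_in):
        if attempt(rng) is not None:
            n_swaps += 1
    null = np.empty(n_perm)
    for i in range(n_perm):
        for _ in range(attempts_per_step):
            if attempt(rng) is not None:
                n_swaps += 1
        null[i] = fit_coef(gbi_metric(work, metric).to_numpy(float))

    q025, q975 = np.quantile(null, [0.025, 0.975])
    centred = np.abs(null - null.mean())
    p_emp = (1.0 + np.sum(centred >= abs(observed - null.mean()))) / (n_perm + 1.0)
    return PermutationTestResult(
        metric=metric, observed=observed, null=null, n_perm=n_perm,
        significant=bool(observed < q025 or observed > q975),
        p_empirical=float(p_emp), null_q025=float(q025), null_q975=float(q975),
        n_swaps_total=n_swaps,
    )


@dataclass
class SubpopRegressionResult:
    """OLS of scrounger proportion on subpopulation size."""

    slope: float
    t: float
    p: float
    r2: float
    year_coefs: dict[str, float]
    n: int


def subpop_regression(
    table: pd.DataFrame,
    prop_col: str = "proportion_scroungers",
    size_col: str = "subpop_size",
    year_col: str | None = "year",
) -> SubpopRegressionResult:
    """Regress the per-replicate proportion of scrounger-labelled birds on
    subpopulation size (all birds detected at puzzle-boxes in the
    replicate), with year as a categorical control when present.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 replicates")
    size = table[size_col].to_numpy(float)
    if size.std() == 0:
        raise ValueError("subpopulation size is constant (rank-deficient design)")
    X = pd.DataFrame({"subpop_size": size})
    year_terms: list[str] = []
    if year_col is not None and year_col in table and table[year_col].nunique() > 1:
        dummies = pd.get_dummies(
            table[year_col].astype(str), prefix="year", drop_first=True
        ).astype(float)
        year_terms = list(dummies.columns)
        X = pd.concat([X, dummies.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise ValueError("rank-deficient design in subpopulation regression")
    fit = sm.OLS(table[prop_col].to_numpy(float), X).fit()
    return SubpopRegressionResult(
        slope=float(fit.params["subpop_size"]),
        t=float(fit.tvalues["subpop_size"]),
        p=float(fit.pvalues["subpop_size"]),
        r2=float(fit.rsquared),
        year_coefs={c: float(fit.params[c]) for c in year_terms},
        n=len(table),
    )


def simulate_glmm_dataset(
    n_birds: int = 300,
    n_replicates: int = 4,
    beta: dict[str, float] | None = None,
    intercept: float = -0.7,
    sigma2: float = 0.25,
    mean_visits: float = 100.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a per-bird count table from the scrounging mixed model.

    Covariates (``latency_to_learn``, ``first_contact``, ``exploration``)
    are standard normal, so the configured ``beta`` values are already on
    the standardized scale the fitter reports. Used for parameter-recovery
    and type-I-error studies of :func:`fit_binomial_glmm`.
    """
    rng = np.random.default_rng() if rng is None else rng
    beta = beta or {}
    covs = ["latency_to_learn", "first_contact", "exploration"]
    df = pd.DataFrame({c: rng.normal(size=n_birds) for c in covs})
    rep = rng.integers(0, n_replicates, n_birds)
    df["replicate"] = [f"R{r}" for r in rep]
    u = rng.normal(0.0, np.sqrt(sigma2), n_replicates)
    eta = intercept + u[rep]
    for c in covs:
        eta = eta + beta.get(c, 0.0) * df[c].to_numpy()
    mtot = rng.poisson(mean_visits, n_birds) + 5
    df["n_scrounges"] = rng.binomial(mtot, expit(eta))
    df["n_solves"] = mtot - df["n_scrounges"]
    df["bird_id"] = [f"B{i:04d}" for i in range(n_birds)]
    return df


def simulate_event_level(
    n_birds: int = 200,
    events_per_bird: int = 100,
    v_ind: float = 1.0,
    intercept: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate event-level binary scrounge/solve outcomes with a known
    among-bird latent variance, for repeatability recovery studies.

    On the latent scale the true repeatability is
    v_ind / (v_ind + pi^2/3).
    """
    rng = np.random.default_rng() if rng is None else rng
    u = rng.normal(0.0, np.sqrt(v_ind), n_birds)
    p = expit(intercept + u)
    rows = {
        "bird_id": np.repeat([f"B{i:04d}" for i in range(n_birds)], events_per_bird),
        "is_scrounge": rng.binomial(
            1, np.repeat(p, events_per_bird)
        ),
    }
    return pd.DataFrame(rows)
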