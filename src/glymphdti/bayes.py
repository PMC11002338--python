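"""Bayesian model-averaged ANCOVA with JZS (Zellner-Siow) priors.

For a response y and additive candidate models built from subsets of the
predictors (continuous covariates + one 2-level factor), each model M is
scored against the intercept-only null by the g-prior marginal-likelihood
ratio

    BF10(M) = int_0^inf (1+g)^{(n-1-k)/2} [1 + g(1 - R2_M)]^{-(n-1)/2} pi(g) dg

where k is the number of design columns of M beyond the intercept, R2_M its
coefficient of determination on the centred design, and pi(g) the
Zellner-Siow inverse-gamma(1/2, n r^2 / 2) mixing density.  A single shared
g is used per model with an effective r^2 equal to the mean of the included
terms' squared prior scales (Cauchy scale r = 0.5 for the factor,
r = sqrt(2)/4 for continuous covariates, the conventional ANOVA defaults —
note that software using one g per term class can differ in the second
decimal).

Model-averaged quantities follow: posterior model probabilities, the
BF_M change-from-prior-odds factor per model, and per-predictor inclusion
Bayes factors (the change from prior to posterior inclusion odds).  All
accumulation is done in log space; the integral is evaluated on a
log-transformed axis after locating and subtracting the integrand's peak,
so Bayes factors up to e+-700 are representable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.special import gammaln, logsumexp

__all__ = [
    "Predictor",
    "ModelSpace",
    "BayesConfig",
    "BayesANCOVAResult",
    "enumerate_models",
    "design_matrix",
    "model_bf10",
    "posterior_model_probs",
    "bf_m",
    "inclusion_bf",
    "run_bayes_ancova",
    "validate_cohort_table",
]

R_FACTOR_DEFAULT = 0.5
R_CONTINUOUS_DEFAULT = math.sqrt(2.0) / 4.0


@dataclass(frozen=True)
class Predictor:
    """A model term: a continuous covariate or a 2-level factor."""

    name: str
    kind: str  # 'continuous' | 'factor'

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "factor"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")


@dataclass
class ModelSpace:
    """All additive submodels of a predictor set, with prior probabilities."""

    predictors: tuple[Predictor, ...]
    models: tuple[tuple[str, ...], ...]  # each model = sorted predictor names
    priors: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.priors.sum() - 1.0) > 1e-12:
            raise ValueError("model prior probabilities must sum to 1")

    def model_name(self, model: tuple[str, ...]) -> str:
        return " + ".join(model) if model else "null"


def enumerate_models(predictors) -> ModelSpace:
    """All 2^p additive subsets (including the null) under a uniform prior."""
    preds = tuple(
        p if isinstance(p, Predictor) else Predictor(*p) for p in predictors
    )
    names = [p.name for p in preds]
    if len(set(names)) != len(names):
        raise ValueError("duplicate predictor names")
    models = []
    for r in range(len(preds) + 1):
        for combo in itertools.combinations(names, r):
            models.append(tuple(combo))
    priors = np.full(len(models), 1.0 / len(models))
    return ModelSpace(predictors=preds, models=tuple(models), priors=priors)


@dataclass
class BayesConfig:
    """Prior scales and quadrature settings."""

    r_factor: float = R_FACTOR_DEFAULT
    r_continuous: float = R_CONTINUOUS_DEFAULT
    quad_rel_tol: float = 1e-10
    quad_limit: int = 200


# ---------------------------------------------------------------------------
# Design


def design_matrix(
    table: pd.DataFrame, model: tuple[str, ...], predictors: tuple[Predictor, ...], dv: str
) -> tuple[np.ndarray, np.ndarray]:
    """Centred design matrix (without intercept column) and raw response.

    Continuous covariates are standardised (mean 0, sample sd 1, ddof=1);
    the 2-level factor is coded sum-to-zero (-1/2, +1/2 by sorted level
    order) and then mean-centred so every column is orthogonal to the
    intercept.  The response is left on its raw scale.
    """
    kinds = {p.name: p.kind for p in predictors}
    cols = []
    for name in model:
        x = table[name].to_numpy()
        if kinds[name] == "continuous":
            x = np.asarray(x, dtype=float)
            sd = x.std(ddof=1)
            if sd <= 0:
                raise ValueError(f"covariate {name!r} has zero variance")
            col = (x - x.mean()) / sd
        else:
            levels = sorted(pd.unique(x))
            if len(levels) != 2:
                raise ValueError(f"factor {name!r} must have exactly 2 levels, got {levels}")
            col = np.where(x == levels[0], -0.5, 0.5)
            col = col - col.mean()
        cols.append(col)
    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    y = table[dv].to_numpy(dtype=float)
    return X, y


def _r_squared(X: np.ndarray, y: np.ndarray) -> float:
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst <= 0:
        raise ValueError("response has zero variance")
    if X.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
    resid = yc - X @ beta
    return 1.0 - float(resid @ resid) / sst


# ---------------------------------------------------------------------------
# JZS Bayes factor


def _log_jzs_integrand(log_g: np.ndarray, n: int, k: int, r2: float, b: float) -> np.ndarray:
    """log of the BF integrand after the g = e^u substitution (du measure).

    b is the inverse-gamma scale n*r_eff^2/2; the +log_g term is the
    Jacobian of the substitution.
    """
    u = np.asarray(log_g, dtype=float)
    a = 0.5
    # stable forms: log1p(e^u) via logaddexp; b/g = b e^{-u} clipped
    log_prior = a * math.log(b) - gammaln(a) - (a + 1.0) * u - b * np.exp(-np.clip(u, -700, 700))
    log_lik = 0.5 * (n - 1 - k) * np.logaddexp(0.0, u) - 0.5 * (n - 1) * np.logaddexp(
        0.0, u + math.log1p(-r2)
    )
    return log_prior + log_lik + u


def log_bf10_from_r2(n: int, k: int, r2: float, r_eff2: float, cfg: BayesConfig | None = None) -> float:
    """log BF10 for a model with k design columns and fit R2 (shared-g JZS)."""
    cfg = cfg or BayesConfig()
    if k == 0:
        return 0.0
    if n <= k + 2:
        raise ValueError(f"n = {n} too small for k = {k} predictors (need n > k + 2)")
    if r2 >= 1.0 - 1e-12:
        raise ValueError("saturated model (R2 >= 1); Bayes factor undefined")
    b = 0.5 * n * r_eff2

    peak = optimize.minimize_scalar(
        lambda u: -_log_jzs_integrand(np.asarray(u), n, k, r2, b),
        bounds=(-40.0, 40.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    u0 = float(peak.x)
    h0 = float(_log_jzs_integrand(np.asarray(u0), n, k, r2, b))

    # the integrand decays double-exponentially for u -> -inf and at least
    # as e^{-u/2} for u -> +inf; [-60, 300] is far beyond both tails
    val, abserr = integrate.quad(
        lambda u: math.exp(float(_log_jzs_integrand(np.asarray(u), n, k, r2, b)) - h0),
        -60.0,
        300.0,
        points=[u0],
        limit=cfg.quad_limit,
        epsabs=1e-12,
        epsrel=cfg.quad_rel_tol,
    )
    if not np.isfinite(val) or val <= 0 or abserr > 1e-6 * val:
        raise RuntimeError(
            f"quadrature failed for BF10 (value {val:.3e}, abs err {abserr:.3e})"
        )
    return h0 + math.log(val)


def model_bf10(
    table: pd.DataFrame,
    model: tuple[str, ...],
    predictors: tuple[Predictor, ...],
    dv: str,
    cfg: BayesConfig | None = None,
) -> float:
    """BF10 of one additive model against the intercept-only null."""
    cfg = cfg or BayesConfig()
    if not model:
        return 1.0
    X, y = design_matrix(table, model, predictors, dv)
    r2 = _r_squared(X, y)
    kinds = {p.name: p.kind for p in predictors}
    r2s = [
        (cfg.r_factor if kinds[name] == "factor" else cfg.r_continuous) ** 2
        for name in model
    ]
    r_eff2 = float(np.mean(r2s))
    return math.exp(log_bf10_from_r2(len(y), X.shape[1], r2, r_eff2, cfg))


# ---------------------------------------------------------------------------
# Model averaging


def posterior_model_probs(space: ModelSpace, bf10: np.ndarray) -> np.ndarray:
    """P(M|D) = P(M) BF10(M) / sum_M' P(M') BF10(M'), in log space."""
    bf10 = np.asarray(bf10, dtype=float)
    if bf10.shape != space.priors.shape:
        raise ValueError("need exactly one Bayes factor per model")
    if not np.all(np.isfinite(bf10)) or np.any(bf10 <= 0):
        raise ValueError("Bayes factors must be finite and positive")
    log_w = np.log(space.priors) + np.log(bf10)
    return np.exp(log_w - logsumexp(log_w))


def bf_m(prior: float, posterior: float) -> float:
    """Change from prior to posterior model odds:
    [P(M|D)/(1-P(M|D))] / [P(M)/(1-P(M))]."""
    if not (0.0 < posterior < 1.0) or not (0.0 < prior < 1.0):
        raise ValueError("degenerate prior or posterior model probability")
    return (posterior / (1.0 - posterior)) / (prior / (1.0 - prior))


def inclusion_bf(
    space: ModelSpace,
    posteriors: np.ndarray,
    predictor: str,
    variant: str = "all",
) -> float:
    """Change from prior to posterior inclusion odds for one predictor.

    'all' ratios the summed odds over every model containing vs. lacking the
    predictor; 'matched' restricts both sums to model pairs differing only
    by the predictor.  With an additive-only model space every model lacking
    p pairs with exactly one containing it, so the two variants coincide;
    they diverge once interaction terms exist.
    """
    if variant not in ("all", "matched"):
        raise ValueError(f"unknown inclusion variant {variant!r}")
    names = [p.name for p in space.predictors]
    if predictor not in names:
        raise ValueError(f"unknown predictor {predictor!r}")
    contains = np.array([predictor in m for m in space.models])
    if variant == "matched":
        order = {n: i for i, n in enumerate(names)}

        def canon(terms):
            # canonical tuple in predictor-declaration order, matching the
            # ordering used by enumerate_models
            return tuple(sorted(terms, key=order.__getitem__))

        without = {canon(m) for m in space.models if predictor not in m}
        paired_with = {canon(set(m) | {predictor}) for m in space.models if predictor not in m}
        keep = np.array(
            [canon(m) in without or canon(m) in paired_with for m in space.models]
        )
    else:
        keep = np.ones(len(space.models), dtype=bool)
    post_in = posteriors[contains & keep].sum()
    post_out = posteriors[~contains & keep].sum()
    prior_in = space.priors[contains & keep].sum()
    prior_out = space.priors[~contains & keep].sum()
    if min(post_in, post_out, prior_in, prior_out) <= 0:
        raise ValueError("empty inclusion or exclusion set for predictor")
    return (post_in / post_out) / (prior_in / prior_out)


# ---------------------------------------------------------------------------
# Full analysis


@dataclass
class BayesANCOVAResult:
    """Per-model and per-predictor output of one Bayesian ANCOVA."""

    dv: str
    space: ModelSpace
    bf10: np.ndarray
    posteriors: np.ndarray
    bf_m: np.ndarray
    inclusion: dict  # {predictor: {"all": float, "matched": float}}
    n: int
    n_dropped: int
    config: BayesConfig = field(default_factory=BayesConfig)

    def model_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [self.space.model_name(m) for m in self.space.models],
                "prior": self.space.priors,
                "bf10": self.bf10,
                "posterior": self.posteriors,
                "bf_m": self.bf_m,
            }
        )

    def to_dict(self) -> dict:
        return {
            "dv": self.dv,
            "n": self.n,
            "n_dropped": self.n_dropped,
            "models": self.model_table().to_dict(orient="records"),
            "inclusion": self.inclusion,
            "config": {
                "r_factor": self.config.r_factor,
                "r_continuous": self.config.r_continuous,
                "quad_rel_tol": self.config.quad_rel_tol,
            },
        }


def validate_cohort_table(
    table: pd.DataFrame, columns, factor: str
) -> tuple[pd.DataFrame, int]:
    """Listwise-drop rows with missing modelled values; check the factor."""
    sub = table.dropna(subset=list(columns))
    n_dropped = len(table) - len(sub)
    levels = pd.unique(sub[factor])
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels, got {list(levels)}")
    return sub.reset_index(drop=True), n_dropped


def run_bayes_ancova(
    table: pd.DataFrame,
    dv: str,
    covariates=("age", "EDSS"),
    factor: str = "group",
    config: BayesConfig | None = None,
) -> BayesANCOVAResult:
    """Enumerate models -> BF10 per model -> posteriors -> BF_M -> inclusion BFs.

    Deterministic given the table and configuration.
    """
    config = config or BayesConfig()
    predictors = [Predictor(c, "continuous") for c in covariates] + [Predictor(factor, "factor")]
    modeled = list(covariates) + [factor, dv]
    table, n_dropped = validate_cohort_table(table, modeled, factor)
    space = enumerate_models(predictors)
    bf10 = np.array(
        [model_bf10(table, m, space.predictors, dv, config) for m in space.models]
    )
    posteriors = posterior_model_probs(space, bf10)
    bfm = np.array([bf_m(p, q) for p, q in zip(space.priors, posteriors)])
    inclusion = {
        p.name: {
            "all": inclusion_bf(space, posteriors, p.name, "all"),
            "matched": inclusion_bf(space, posteriors, p.name, "matched"),
        }
        for p in space.predictors
    }
    return BayesANCOVAResult(
        dv=dv,
        space=space,
        bf10=bf10,
        posteriors=posteriors,
        bf_m=bfm,
        inclusion=inclusion,
        n=len(table),
        n_dropped=n_dropped,
        config=config,
    )
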