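"""Mixed-effects response models and the flee/stay group comparison.

Two models carry the inference:

* a linear mixed model of log cumulative distance (immediate or delayed)
  on understorey cover, familiarity, dog density, beater density and gunshot
  count, with a per-individual random intercept —
  ``log(Dist) = mu + a*Bush + b*Fam + c*Dogs + d*Beat + r*Shot + u_ind + eps``;
* a logistic mixed model of the short-return indicator on hunting condition,
  familiarity and their interaction, with a per-individual random intercept.

The fitting contract is point estimate plus 95% and 75% intervals.  The
linear model is fitted by REML (statsmodels MixedLM); the logistic model by
maximum likelihood with Gauss-Hermite quadrature over the random intercept,
Wald intervals from the numerical Hessian.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess

Z95 = stats.norm.ppf(0.975)
Z75 = stats.norm.ppf(0.875)

DISTANCE_TERMS = ("intercept", "bush", "fam", "dogs_per_ha", "beaters_per_ha", "gunshots")
RETURN_TERMS = ("intercept", "hunt", "fam", "hunt_fam")


class DegenerateDesignError(ValueError):
    """A covariate is constant (or the design otherwise singular)."""


class SeparationError(ValueError):
    """The binary response admits no finite ML estimate."""


@dataclass
class FitResult:
    """Coefficients with 95%/75% intervals plus variance components.

    ``table`` columns: term, estimate, se, l95, u95, l75, u75.
    """

    table: pd.DataFrame
    sigma_u: float
    resid_sd: float | None
    n_events: int
    n_individuals: int
    converged: bool
    backend: str
    separation_flag: bool = False
    warnings: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def interval(self, term: str, level: int = 95) -> tuple[float, float]:
        row = self.table.set_index("term").loc[term]
        return float(row[f"l{level}"]), float(row[f"u{level}"])


def _interval_table(terms, est, se) -> pd.DataFrame:
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    return pd.DataFrame(
        {
            "term": list(terms),
            "estimate": est,
            "se": se,
            "l95": est - Z95 * se,
            "u95": est + Z95 * se,
            "l75": est - Z75 * se,
            "u75": est + Z75 * se,
        }
    )


def _check_design(df: pd.DataFrame, cols) -> None:
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        if not np.isfinite(v).all():
            raise ValueError(f"covariate {c!r} contains non-finite values")
        if np.ptp(v) == 0:
            raise DegenerateDesignError(f"covariate {c!r} is constant")


def fit_distance_model(
    events: pd.DataFrame, response: str = "immediate"
) -> FitResult:
    """Linear mixed model of log cumulative distance on the five hunt
    covariates with a per-individual random intercept.

    ``events`` needs columns ``dist_immediate_m`` (or ``dist_delayed_m``),
    ``bush``, ``fam``, ``dogs_per_ha``, ``beaters_per_ha``, ``gunshots`` and
    ``individual_id``.  Distances must be positive.  With a single
    individual the model degrades to a fixed-intercept OLS fit (sigma_u
    pinned to 0, warning recorded).
    """
    col = {"immediate": "dist_immediate_m", "delayed": "dist_delayed_m"}[response]
    df = events.dropna(subset=[col, *DISTANCE_TERMS[1:], "individual_id"]).copy()
    if len(df) < 10:
        raise ValueError("need at least 10 events to fit the distance model")
    if (df[col] <= 0).any():
        raise ValueError("distances must be positive to take logarithms")
    _check_design(df, DISTANCE_TERMS[1:])
    y = np.log(df[col].to_numpy(dtype=float))
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in DISTANCE_TERMS[1:]]
    )
    groups = df["individual_id"].to_numpy()
    n_ind = len(np.unique(groups))
    warns: list[str] = []
    if n_ind < 2:
        warns.append("single individual: fixed-intercept regression, sigma_u pinned to 0")
        import statsmodels.api as sm

        res = sm.OLS(y, X).fit()
        table = _interval_table(DISTANCE_TERMS, res.params, res.bse)
        return FitResult(
            table, 0.0, float(np.sqrt(res.scale)), len(df), n_ind, True, "ols", warnings=warns
        )
    # fit on standardized covariates for conditioning, then transform back
    means = X[:, 1:].mean(axis=0)
    sds = X[:, 1:].std(axis=0, ddof=0)
    Xs = np.column_stack([X[:, 0], (X[:, 1:] - means) / sds])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = MixedLM(y, Xs, groups=groups)
        res = model.fit(reml=True)
    warns += [str(w.message) for w in caught]
    k = X.shape[1]
    A = np.eye(k)
    A[0, 1:] = -means / sds
    A[np.arange(1, k), np.arange(1, k)] = 1.0 / sds
    est = A @ np.asarray(res.fe_params)
    cov_fe = np.asarray(res.cov_params())[:k, :k]
    se = np.sqrt(np.clip(np.diag(A @ cov_fe @ A.T), 0.0, None))
    table = _interval_table(DISTANCE_TERMS, est, se)
    sigma_u = float(np.sqrt(max(float(np.asarray(res.cov_re)[0, 0]), 0.0)))
    return FitResult(
        table,
        sigma_u,
        float(np.sqrt(res.scale)),
        len(df),
        n_ind,
        bool(res.converged),
        "mixedlm-reml",
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# logistic GLMM by Gauss-Hermite quadrature


def _glmm_neg_loglik(params, X, y, group_idx, n_groups, nodes, log_wts):
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta = X @ beta
    shift = np.sqrt(2.0) * sigma * nodes  # (K,)
    z = eta[:, None] + shift[None, :]  # (N, K)
    # log Bernoulli(y | logistic(z))
    ll = np.where(y[:, None] == 1, -np.logaddexp(0.0, -z), -np.logaddexp(0.0, z))
    per_group = np.zeros((n_groups, len(nodes)))
    np.add.at(per_group, group_idx, ll)
    group_ll = logsumexp(per_group + log_wts[None, :], axis=1) - 0.5 * np.log(np.pi)
    return -float(group_ll.sum())


def fit_return_model(records: pd.DataFrame, n_quadrature: int = 30) -> FitResult:
    """Logistic mixed model of the short-return indicator on hunting
    condition, familiarity and their interaction.

    ``records`` needs columns ``short_return`` (0/1; rows with None/NaN are
    dropped), ``hunt`` (1 = post-hunt), ``fam`` and ``individual_id``.  The
    marginal likelihood integrates the per-individual random intercept by
    Gauss-Hermite quadrature; intervals are Wald.  A constant response
    raises :class:`SeparationError`; exploding estimates set
    ``separation_flag``.
    """
    df = records.dropna(subset=["short_return", "hunt", "fam", "individual_id"]).copy()
    y = df["short_return"].to_numpy(dtype=float)
    if len(df) < 10:
        raise ValueError("need at least 10 resolved records")
    if len(np.unique(y)) < 2:
        raise SeparationError("all responses identical: no finite ML estimate")
    if df["hunt"].nunique() < 2:
        raise DegenerateDesignError("both conditions must be present")
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["hunt"].to_numpy(dtype=float),
            df["fam"].to_numpy(dtype=float),
            (df["hunt"] * df["fam"]).to_numpy(dtype=float),
        ]
    )
    groups, group_idx = np.unique(df["individual_id"].to_numpy(), return_inverse=True)
    nodes, wts = np.polynomial.hermite.hermgauss(n_quadrature)
    log_wts = np.log(wts)

    # plain logistic start values
    from statsmodels.api import GLM, families

    try:
        beta0 = GLM(y, X, family=families.Binomial()).fit().params
    except Exception:
        beta0 = np.zeros(X.shape[1])
    x0 = np.concatenate([beta0, [np.log(0.5)]])
    args = (X, y, group_idx, len(groups), nodes, log_wts)
    opt = optimize.minimize(
        _glmm_neg_loglik,
        x0,
        args=args,
        method="L-BFGS-B",
        bounds=[(-30, 30)] * X.shape[1] + [(-6.0, 3.0)],
    )
    params = opt.x
    H = approx_hess(params, _glmm_neg_loglik, args=args)
    separation = bool(np.abs(params[:-1]).max() > 12)
    warns: list[str] = []
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        separation = True
        se_all = np.full(len(params), np.inf)
    if separation:
        warns.append("possible complete separation: interval blow-up")
    table = _interval_table(RETURN_TERMS, params[:-1], se_all[:-1])
    return FitResult(
        table,
        float(np.exp(params[-1])),
        None,
        len(df),
        len(groups),
        bool(opt.success),
        "glmm-gauss-hermite-ml",
        separation_flag=separation,
        warnings=warns,
    )


@dataclass
class GroupComparison:
    statistic: float
    df: int
    pvalue: float
    n_fleeing: int
    n_staying: int
    median_fleeing: float
    median_staying: float


def compare_group_distances(
    events: pd.DataFrame, response: str = "immediate"
) -> GroupComparison:
    """Pooled-variance two-sample t test of cumulative distances between the
    staying and fleeing groups (statistic oriented staying - fleeing, with
    df = n1 + n2 - 2)."""
    col = {"immediate": "dist_immediate_m", "delayed": "dist_delayed_m"}[response]
    df_ = events.dropna(subset=[col, "classification"])
    flee = df_.loc[df_["classification"] == "fleeing", col].to_numpy(dtype=float)
    stay = df_.loc[df_["classification"] == "staying", col].to_numpy(dtype=float)
    if len(flee) < 2 or len(stay) < 2:
        raise ValueError("both groups need at least 2 events")
    t, p = stats.ttest_ind(stay, flee, equal_var=True)
    return GroupComparison(
        statistic=float(t),
        df=len(flee) + len(stay) - 2,
        pvalue=float(p),
        n_fleeing=len(flee),
        n_staying=len(stay),
        median_fleeing=float(np.median(flee)),
        median_staying=float(np.median(stay)),
    )
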