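"""Logistic-regression inference linking persistence to rarity status.

The model asks whether occurrence — the number of lakes (1-5) or the number
of seasons (1-4) a species was detected in — predicts the probability that a
low-abundance species is rare throughout the region (coded 1) rather than
rare locally (coded 0), adjusting for body size (log10 mean wet weight in
grams).  Persistence is treatment-coded as a factor with the lowest observed
level as reference, and the overall factor effect is tested with a joint
Wald chi-square on the dummy block.  Space and time are always fitted in
separate models.

Fitting is by Newton–Raphson / iteratively reweighted least squares with a
step-halving safeguard; the covariance is the inverse observed Fisher
information X'WX at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .data import ValidationError
from .rarity import StatusAssignment

__all__ = [
    "DesignInfo",
    "encode_design",
    "LogisticFit",
    "fit_logistic_irls",
    "WaldResult",
    "wald_factor_test",
    "chi_square_upper_tail",
    "predict_probability_grid",
    "LikelihoodRatioResult",
    "interaction_check",
    "with_interaction",
]

RESPONSE_POSITIVE = "rare_throughout"
RESPONSE_NEGATIVE = "rare_locally"


@dataclass(frozen=True)
class DesignInfo:
    """Design matrix plus the factor metadata needed for prediction."""

    X: pd.DataFrame
    y: pd.Series
    factor: str
    levels_observed: tuple[int, ...]
    reference_level: int

    @property
    def dummy_names(self) -> tuple[str, ...]:
        return tuple(f"{self.factor}[{lvl}]" for lvl in self.levels_observed if lvl != self.reference_level)


def encode_design(
    assignment: StatusAssignment,
    traits: pd.DataFrame,
    profiles: pd.DataFrame,
    factor: str = "lakes",
    max_level: int | None = None,
) -> DesignInfo:
    """Build the design matrix for one persistence factor.

    Rows are the species classified rare_locally or rare_throughout (excluded
    and common species never enter).  Columns: intercept, log10 mean wet
    weight, and one indicator per observed factor level above the reference
    (the lowest observed level).  Unobserved levels get no column, shrinking
    the Wald degrees of freedom accordingly.
    """
    if factor not in ("lakes", "seasons"):
        raise ValueError("factor must be 'lakes' or 'seasons'")
    col = "n_lakes" if factor == "lakes" else "n_seasons"
    if max_level is None:
        max_level = 5 if factor == "lakes" else 4

    status = assignment.status
    included = status.index[status.isin([RESPONSE_NEGATIVE, RESPONSE_POSITIVE])]
    if len(included) == 0:
        raise ValidationError("no rare species to model")
    missing_prof = [s for s in included if s not in profiles.index]
    if missing_prof:
        raise ValidationError(f"species lacking occurrence profiles: {missing_prof[:10]}")
    weights = traits["mean_wet_weight_g"].reindex(included)
    if weights.isna().any() or (weights <= 0).any():
        bad = list(included[weights.isna() | (weights <= 0)][:10])
        raise ValidationError(f"species lacking a positive mean weight: {bad}")

    y = (status.loc[included] == RESPONSE_POSITIVE).astype(float)
    if y.nunique() < 2:
        raise ValidationError("response is constant: both rarity statuses are required")

    levels = profiles.loc[included, col].astype(int)
    out_of_range = levels[(levels < 1) | (levels > max_level)]
    if len(out_of_range):
        raise ValidationError(
            f"{factor} level outside 1..{max_level} for {list(out_of_range.index[:10])}"
        )
    observed = tuple(int(v) for v in sorted(levels.unique()))
    reference = observed[0]

    X = pd.DataFrame(index=included)
    X["intercept"] = 1.0
    X["log10_weight"] = np.log10(weights.astype(float))
    for lvl in observed:
        if lvl == reference:
            continue
        X[f"{factor}[{lvl}]"] = (levels == lvl).astype(float)
    return DesignInfo(X=X, y=y, factor=factor, levels_observed=observed, reference_level=reference)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with observed-information covariance."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_iter: int
    converged: bool
    separation_flag: bool
    n_obs: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = float(special.ndtri(0.5 + level / 2.0))
        se = self.bse
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se}
        )


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_irls(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    separation_bound: float = 15.0,
) -> LogisticFit:
    """Fit a Bernoulli GLM with logit link by Newton–Raphson (IRLS).

    Convergence requires both the score sup-norm and the relative step
    sup-norm to fall below ``tol``.  If the likelihood would decrease, the
    Newton step is halved (up to 30 times).  Coefficients drifting beyond
    ``separation_bound`` in absolute value while the likelihood still
    improves raise the ``separation_flag`` — the hallmark of (quasi-)complete
    separation, under which maximum-likelihood estimates do not exist.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float).ravel()
    if Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    if not set(np.unique(ya)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    n, p = Xa.shape
    if np.linalg.matrix_rank(Xa) < p:
        raise ValidationError("design matrix is not of full column rank")

    beta = np.zeros(p)
    eta = Xa @ beta
    ll = _loglik(eta, ya)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = special.expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        score = Xa.T @ (ya - mu)
        info = (Xa * w[:, None]).T @ Xa
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("singular information matrix during IRLS") from exc
        # step halving: never accept a likelihood decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_cand = _loglik(Xa @ cand, ya)
            if ll_cand >= ll - 1e-12:
                break
            factor /= 2.0
        beta_new = beta + factor * step
        eta = Xa @ beta_new
        ll_new = _loglik(eta, ya)
        step_norm = np.max(np.abs(beta_new - beta)) / (1.0 + np.max(np.abs(beta_new)))
        beta, ll = beta_new, ll_new
        if np.max(np.abs(beta)) > separation_bound:
            separation = True
            break
        mu = special.expit(eta)
        score_norm = np.max(np.abs(Xa.T @ (ya - mu)))
        if score_norm < tol and step_norm < tol:
            converged = True
            break

    mu = special.expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (Xa * w[:, None]).T @ Xa
    cov = np.linalg.inv(info)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=ll,
        n_iter=it,
        converged=converged and not separation,
        separation_flag=separation,
        n_obs=n,
    )


@dataclass(frozen=True)
class WaldResult:
    """Joint Wald chi-square test of a coefficient block."""

    statistic: float
    df: int
    p: float


def wald_factor_test(fit: LogisticFit, block: Sequence[str] | Sequence[int]) -> WaldResult:
    """Joint Wald test chi2 = b' (V_bb)^-1 b on a coefficient block.

    For a treatment-coded factor with m observed levels the block is its
    m - 1 dummy coefficients, giving df = m - 1.
    """
    block = list(block)
    if len(block) == 0:
        raise ValueError("empty coefficient block")
    if all(isinstance(b, (int, np.integer)) for b in block):
        names = [fit.params.index[int(b)] for b in block]
    else:
        names = [str(b) for b in block]
        unknown = [nm for nm in names if nm not in fit.params.index]
        if unknown:
            raise ValueError(f"unknown coefficients {unknown}")
    b = fit.params.loc[names].to_numpy()
    V = fit.cov.loc[names, names].to_numpy()
    try:
        solved = np.linalg.solve(V, b)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular covariance sub-block in Wald test") from exc
    stat = float(b @ solved)
    df = len(block)
    return WaldResult(statistic=stat, df=df, p=chi_square_upper_tail(stat, df))


def chi_square_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability P(Chi2_df >= x) = Q(df/2, x/2).

    Computed as the regularized upper incomplete gamma function.
    """
    x = float(x)
    if not np.isfinite(x) or x < 0:
        raise ValueError(f"x must be a finite non-negative real, got {x}")
    if df < 1 or int(df) != df:
        raise ValueError(f"df must be a positive integer, got {df}")
    return float(special.gammaincc(df / 2.0, x / 2.0))


def predict_probability_grid(
    fit: LogisticFit,
    design: DesignInfo,
    weights_log10: Iterable[float],
    levels: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Predicted P(rare throughout) over a body-size grid at each factor level.

    Returns tidy (log10_weight, level, probability) rows; probabilities are
    the inverse logit of the linear predictor.
    """
    if not fit.converged:
        raise ValidationError("cannot predict from a non-converged fit")
    lvls = tuple(levels) if levels is not None else design.levels_observed
    unknown = [l for l in lvls if l not in design.levels_observed]
    if unknown:
        raise ValidationError(f"levels never observed in the fit: {unknown}")
    rows = []
    for w in weights_log10:
        for lvl in lvls:
            eta = fit.params["intercept"] + fit.params["log10_weight"] * float(w)
            name = f"{design.factor}[{lvl}]"
            if name in fit.params.index:
                eta += fit.params[name]
            rows.append((float(w), int(lvl), float(special.expit(eta))))
    return pd.DataFrame(rows, columns=["log10_weight", "level", "probability"])


@dataclass(frozen=True)
class LikelihoodRatioResult:
    statistic: float
    df: int
    p: float
    converged: bool


def with_interaction(design: DesignInfo) -> pd.DataFrame:
    """Augment a design with body-size x factor-dummy interaction columns."""
    X = design.X.copy()
    for name in design.dummy_names:
        X[f"log10_weight:{name}"] = X["log10_weight"] * X[name]
    return X


def interaction_check(
    X_reduced: pd.DataFrame,
    X_full: pd.DataFrame,
    y: pd.Series | np.ndarray,
    **fit_kwargs,
) -> LikelihoodRatioResult:
    """Likelihood-ratio test of nested logistic designs (e.g. an interaction).

    The reduced design's columns must be a subset of the full design's.
    The statistic 2(l_full - l_reduced) is non-negative by construction and
    referred to a chi-square with df = number of added columns.
    """
    reduced_cols = set(X_reduced.columns)
    full_cols = set(X_full.columns)
    if not reduced_cols <= full_cols:
        raise ValueError("designs are not nested: reduced columns must be a subset of full")
    df = len(full_cols - reduced_cols)
    fit_r = fit_logistic_irls(X_reduced, y, **fit_kwargs)
    if df == 0:
        return LikelihoodRatioResult(0.0, 0, 1.0, fit_r.converged)
    fit_f = fit_logistic_irls(X_full, y, **fit_kwargs)
    stat = max(0.0, 2.0 * (fit_f.loglik - fit_r.loglik))
    p = chi_square_upper_tail(stat, df) if df > 0 else 1.0
    return LikelihoodRatioResult(stat, df, p, fit_r.converged and fit_f.converged)
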