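"""Random-intercept mixed models for pecking performance and kinematics.

Two model families are implemented from scratch:

* a binomial GLMM with logit link (pecking outcome ~ phase, individual as a
  random intercept), fitted by maximizing the exact marginal likelihood with
  the per-group random intercept integrated out by *adaptive* Gauss-Hermite
  quadrature: the quadrature nodes are recentred at each group's conditional
  mode and rescaled by the conditional curvature (a Laplace rescaling), so a
  modest number of nodes (15 by default) gives near-exact integrals;
* a Gaussian linear mixed model (grasping onset ~ phase + movement distance +
  mean acceleration, individual as a random intercept), fitted by profiling
  the fixed effects and the residual variance out of the (restricted)
  likelihood and optimizing the single variance ratio theta = sigma_u^2 /
  sigma_e^2 numerically.

On top of the fits: likelihood-ratio tests (ML fits only, Type-II term
dropping), a Pearson dispersion ratio for the binomial model, per-phase Wald
95% CIs compared against the control phase, and Nakagawa-style marginal /
conditional R^2.

Fixed-effect standard errors and the vcov used for CIs condition on the
estimated variance components, as is conventional for mixed models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import PHASES


class ModelError(ValueError):
    pass


class DegenerateResponseWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# model specification and design matrices


@dataclass
class ModelSpec:
    """Declarative model: response ~ fixed_terms + (1 | grouping).

    ``fixed_terms`` is a list of column names (factors are detected from
    non-numeric dtype) and pairwise interactions written ``"a:b"``.
    ``family`` is ``"binomial"`` (logit link) or ``"gaussian"``. Where a
    phase factor appears, ``control`` is the reference level.
    """

    response: str
    fixed_terms: list
    grouping: str
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "gaussian"):
            raise ModelError(f"unknown family {self.family!r}")


def _is_factor(s: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(s) or pd.api.types.is_bool_dtype(s)


def _levels(s: pd.Series) -> list:
    vals = list(pd.unique(s.astype(str)))
    if set(vals) <= set(PHASES):
        ordered = [p for p in PHASES if p in vals]
    else:
        ordered = sorted(vals)
    if "control" in ordered:
        ordered = ["control"] + [v for v in ordered if v != "control"]
    return ordered


def _encode_factor(s: pd.Series, coding: str) -> tuple[np.ndarray, list[str]]:
    levels = _levels(s)
    ref = levels[0]
    vals = s.astype(str).to_numpy()
    cols, names = [], []
    for lv in levels[1:]:
        col = (vals == lv).astype(float)
        if coding == "sum":
            col = col - (vals == ref).astype(float)
        cols.append(col)
        names.append(lv)
    return np.column_stack(cols) if cols else np.empty((len(s), 0)), names


def build_design(
    data: pd.DataFrame, spec: ModelSpec, coding: str = "treatment"
) -> tuple[np.ndarray, list[str], dict]:
    """Design matrix with intercept; returns (X, column names, term -> cols).

    ``coding`` is ``"treatment"`` (reference-level dummies, default) or
    ``"sum"``; LRT statistics are invariant to this choice.
    """
    n = len(data)
    columns: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    term_cols: dict = {"Intercept": [0]}

    def main_effect(term: str) -> tuple[np.ndarray, list[str]]:
        s = data[term]
        if _is_factor(s):
            block, lvls = _encode_factor(s, coding)
            return block, [f"{term}[{lv}]" for lv in lvls]
        return s.to_numpy(dtype=float)[:, None], [term]

    for term in spec.fixed_terms:
        if ":" in term:
            a, b = term.split(":")
            A, an = main_effect(a)
            B, bn = main_effect(b)
            block = np.column_stack(
                [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
            ) if A.shape[1] and B.shape[1] else np.empty((n, 0))
            bnames = [f"{x}:{y}" for x in an for y in bn]
        else:
            if term not in data.columns:
                raise ModelError(f"column {term!r} not in data")
            block, bnames = main_effect(term)
        idx = list(range(len(names), len(names) + block.shape[1]))
        term_cols[term] = idx
        columns.append(block)
        names.extend(bnames)
    X = np.column_stack(columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("design matrix is rank deficient")
    return X, names, term_cols


def _response(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    y = data[spec.response]
    if _is_factor(y):
        vals = set(map(str, pd.unique(y)))
        if vals <= {"success", "failure"}:
            return (y.astype(str) == "success").to_numpy(dtype=float)
        raise ModelError(f"cannot interpret response values {sorted(vals)}")
    return y.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# fit container


@dataclass
class MixedModelFit:
    """Estimates and derived quantities of one fitted mixed model."""

    beta: np.ndarray
    se_beta: np.ndarray
    vcov_beta: np.ndarray
    names: list
    term_cols: dict
    sigma_u2: float
    sigma_e2: Optional[float]
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    family: str
    method: str  # "ML" or "REML"
    spec: ModelSpec
    coding: str = "treatment"
    separation_warning: bool = False
    n_quad: int = 0

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.names, "estimate": self.beta, "se": self.se_beta}
        )


# ---------------------------------------------------------------------------
# binomial GLMM via adaptive Gauss-Hermite quadrature


def _irls_logistic(X: np.ndarray, y: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Plain logistic regression by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        p = special.expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        WX = X * w[:, None]
        try:
            new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(new)):
            break
        step = new - beta
        beta = new
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.clip(beta, -15, 15)


class _AGQProblem:
    """Vectorized marginal log-likelihood for the binomial random-intercept
    GLMM, with groups processed in parallel."""

    def __init__(self, X, y, groups, n_quad):
        order = np.argsort(groups, kind="stable")
        self.X = X[order]
        self.y = y[order]
        g = groups[order]
        _, starts = np.unique(g, return_index=True)
        self.starts = starts
        self.n_groups = len(starts)
        self.n, self.p = X.shape
        z, w = np.polynomial.hermite.hermgauss(n_quad)
        self.z = z
        self.logw = np.log(w)
        self.n_quad = n_quad

    def _modes(self, eta0, sigma_u2):
        """Conditional modes and curvatures of all groups (vector Newton)."""
        u = np.zeros(self.n_groups)
        for _ in range(100):
            p = special.expit(eta0 + np.repeat(u, np.diff(np.append(self.starts, self.n))))
            grad = np.add.reduceat(self.y - p, self.starts) - u / sigma_u2
            hess = -np.add.reduceat(p * (1 - p), self.starts) - 1.0 / sigma_u2
            step = grad / hess
            step = np.clip(step, -4.0, 4.0)
            u = u - step
            if np.max(np.abs(grad)) < 1e-11:
                break
        p = special.expit(eta0 + np.repeat(u, np.diff(np.append(self.starts, self.n))))
        hess = -np.add.reduceat(p * (1 - p), self.starts) - 1.0 / sigma_u2
        return u, np.sqrt(-1.0 / hess)

    def loglik(self, beta, sigma_u2):
        eta0 = self.X @ beta
        if sigma_u2 < 1e-12:
            ll = self.y * eta0 - np.logaddexp(0.0, eta0)
            return float(ll.sum())
        u_hat, s_hat = self._modes(eta0, sigma_u2)
        # nodes: (groups, quad)
        nodes = u_hat[:, None] + np.sqrt(2.0) * s_hat[:, None] * self.z[None, :]
        reps = np.diff(np.append(self.starts, self.n))
        eta = eta0[:, None] + np.repeat(nodes, reps, axis=0)
        ll_obs = self.y[:, None] * eta - np.logaddexp(0.0, eta)
        ll_grp = np.add.reduceat(ll_obs, self.starts, axis=0)  # (groups, quad)
        log_prior = -0.5 * np.log(2 * np.pi * sigma_u2) - nodes**2 / (2 * sigma_u2)
        log_terms = self.logw[None, :] + self.z[None, :] ** 2 + ll_grp + log_prior
        per_group = np.log(np.sqrt(2.0) * s_hat) + special.logsumexp(log_terms, axis=1)
        return float(per_group.sum())

    def conditional_modes(self, beta, sigma_u2):
        if sigma_u2 < 1e-12:
            return np.zeros(self.n_groups)
        u_hat, _ = self._modes(self.X @ beta, sigma_u2)
        return u_hat


def glmm_group_logliks(X, y, groups, beta, sigma_u2, n_quad=15) -> np.ndarray:
    """Per-group marginal log-likelihood contributions (AGQ). Exposed so the
    quadrature can be validated against brute-force integration."""
    prob = _AGQProblem(np.asarray(X, float), np.asarray(y, float),
                       np.asarray(groups), n_quad)
    eta0 = prob.X @ np.asarray(beta, float)
    if sigma_u2 < 1e-12:
        ll = prob.y * eta0 - np.logaddexp(0.0, eta0)
        return np.add.reduceat(ll, prob.starts)
    u_hat, s_hat = prob._modes(eta0, sigma_u2)
    nodes = u_hat[:, None] + np.sqrt(2.0) * s_hat[:, None] * prob.z[None, :]
    reps = np.diff(np.append(prob.starts, prob.n))
    eta = eta0[:, None] + np.repeat(nodes, reps, axis=0)
    ll_obs = prob.y[:, None] * eta - np.logaddexp(0.0, eta)
    ll_grp = np.add.reduceat(ll_obs, prob.starts, axis=0)
    log_prior = -0.5 * np.log(2 * np.pi * sigma_u2) - nodes**2 / (2 * sigma_u2)
    log_terms = prob.logw[None, :] + prob.z[None, :] ** 2 + ll_grp + log_prior
    return np.log(np.sqrt(2.0) * s_hat) + special.logsumexp(log_terms, axis=1)


def _numeric_hessian(f, x0, h=1e-4):
    k = len(x0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h * h)
    return H


def fit_glmm_binomial(
    data: pd.DataFrame,
    spec: ModelSpec,
    n_quad: int = 15,
    fix_sigma_u: Optional[float] = None,
    coding: str = "treatment",
    max_restarts: int = 2,
) -> MixedModelFit:
    """ML fit of the binomial-logit random-intercept GLMM.

    ``fix_sigma_u`` pins the random-intercept SD (e.g. 0 reduces the model to
    ordinary logistic regression, which is the oracle-equivalence case).
    """
    if spec.family != "binomial":
        raise ModelError("fit_glmm_binomial requires a binomial spec")
    X, names, term_cols = build_design(data, spec, coding)
    y = _response(data, spec)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ModelError("binomial response must be binary")
    if len(np.unique(y)) < 2:
        warnings.warn("response is constant; model is degenerate",
                      DegenerateResponseWarning)
    groups = pd.factorize(data[spec.grouping])[0]
    prob = _AGQProblem(X, y, groups, n_quad)
    p = X.shape[1]

    beta0 = _irls_logistic(X, y)
    if fix_sigma_u is not None:
        def nll(b):
            return -prob.loglik(b, fix_sigma_u**2)

        res = optimize.minimize(nll, beta0, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        beta = res.x
        sigma_u2 = float(fix_sigma_u**2)
        loglik = -res.fun
        converged = bool(res.success)
    else:
        def nll_full(params):
            return -prob.loglik(params[:p], np.exp(2.0 * params[p]))

        best = None
        for attempt in range(max_restarts + 1):
            start_ls = np.log(0.5) if attempt == 0 else np.log(0.1 + attempt)
            x0 = np.append(beta0 if attempt == 0 else beta0 * 0.0, start_ls)
            res = optimize.minimize(
                nll_full, x0, method="L-BFGS-B",
                bounds=[(None, None)] * p + [(np.log(1e-6), np.log(50.0))],
                options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if res.success:
                break
        res = best
        beta = res.x[:p]
        sigma_u2 = float(np.exp(2.0 * res.x[p]))
        if sigma_u2 < 1e-8:
            sigma_u2 = 0.0
        loglik = -res.fun
        converged = bool(res.success)

    # Wald vcov for beta from the full observed information (beta and the
    # variance component jointly); conditioning on sigma_u would understate
    # the intercept uncertainty when groups are few
    vcov = None
    if fix_sigma_u is None and sigma_u2 > 1e-8:
        def nll_all(params):
            return -prob.loglik(params[:p], np.exp(2.0 * params[p]))

        H = _numeric_hessian(nll_all, np.append(beta, 0.5 * np.log(sigma_u2)))
        try:
            vcov = np.linalg.inv(H)[:p, :p]
        except np.linalg.LinAlgError:
            vcov = None
    if vcov is None:
        def nll_beta(b):
            return -prob.loglik(b, sigma_u2)

        H = _numeric_hessian(nll_beta, beta)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.full((p, p), np.nan)
            converged = False
    se = np.sqrt(np.clip(np.diag(vcov), 0, None))
    return MixedModelFit(
        beta=beta, se_beta=se, vcov_beta=vcov, names=names, term_cols=term_cols,
        sigma_u2=sigma_u2, sigma_e2=None, loglik=float(loglik),
        n_obs=len(y), n_groups=prob.n_groups, converged=converged,
        family="binomial", method="ML", spec=spec, coding=coding,
        separation_warning=bool(np.max(np.abs(beta)) > 10), n_quad=n_quad,
    )


# ---------------------------------------------------------------------------
# Gaussian LMM by profiling


class _LMMProblem:
    def __init__(self, X, y, groups):
        order = np.argsort(groups, kind="stable")
        self.X = X[order]
        self.y = y[order]
        g = groups[order]
        _, starts = np.unique(g, return_index=True)
        self.starts = starts
        self.sizes = np.diff(np.append(starts, len(y)))
        self.n_groups = len(starts)
        self.n, self.p = X.shape

    def profile(self, theta, reml=False):
        """GLS at fixed variance ratio theta; returns beta, sigma_e2, loglik."""
        c = theta / (1.0 + theta * self.sizes)  # per group
        Sx = np.add.reduceat(self.X, self.starts, axis=0)  # (G, p)
        Sy = np.add.reduceat(self.y, self.starts)
        A = self.X.T @ self.X - (Sx * c[:, None]).T @ Sx
        b = self.X.T @ self.y - (Sx * c[:, None]).T @ Sy
        beta = np.linalg.solve(A, b)
        r = self.y - self.X @ beta
        rs = np.add.reduceat(r, self.starts)
        q = float(r @ r - np.sum(c * rs**2))
        logdet_v = float(np.sum(np.log1p(theta * self.sizes)))
        if reml:
            df = self.n - self.p
            sigma_e2 = q / df
            _, logdet_a = np.linalg.slogdet(A)
            ll = -0.5 * (df * np.log(2 * np.pi * sigma_e2) + logdet_v
                         + df + logdet_a)
        else:
            sigma_e2 = q / self.n
            ll = -0.5 * (self.n * np.log(2 * np.pi * sigma_e2) + logdet_v + self.n)
        return beta, sigma_e2, float(ll), A


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    method: str = "ML",
    fix_theta: Optional[float] = None,
    coding: str = "treatment",
) -> MixedModelFit:
    """(RE)ML fit of the Gaussian random-intercept LMM.

    The fixed effects and residual variance have closed-form profiles, so the
    numerical search is one-dimensional in theta = sigma_u^2 / sigma_e^2. A
    theta estimate on the zero boundary is reported as sigma_u^2 = 0, where
    the fit coincides with ordinary least squares.
    """
    if spec.family != "gaussian":
        raise ModelError("fit_lmm requires a gaussian spec")
    if method not in ("ML", "REML"):
        raise ModelError("method must be ML or REML")
    X, names, term_cols = build_design(data, spec, coding)
    y = _response(data, spec)
    if not np.all(np.isfinite(y)):
        raise ModelError("response contains non-finite values")
    groups = pd.factorize(data[spec.grouping])[0]
    prob = _LMMProblem(X, y, groups)
    reml = method == "REML"

    if fix_theta is not None:
        theta = float(fix_theta)
        converged = True
    else:
        def negll(log_theta):
            return -prob.profile(np.exp(log_theta), reml)[2]

        res = optimize.minimize_scalar(
            negll, bounds=(np.log(1e-8), np.log(1e6)), method="bounded",
            options={"xatol": 1e-10},
        )
        ll0 = prob.profile(0.0, reml)[2]
        if -res.fun > ll0 + 1e-10:
            theta = float(np.exp(res.x))
        else:
            theta = 0.0
        converged = bool(res.success)

    beta, sigma_e2, ll, A = prob.profile(theta, reml)
    sigma_u2 = theta * sigma_e2
    if theta > 0 and sigma_u2 < 1e-12:
        sigma_u2 = 0.0
    vcov = sigma_e2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(vcov))
    return MixedModelFit(
        beta=beta, se_beta=se, vcov_beta=vcov, names=names, term_cols=term_cols,
        sigma_u2=float(sigma_u2), sigma_e2=float(sigma_e2), loglik=ll,
        n_obs=len(y), n_groups=prob.n_groups, converged=converged,
        family="gaussian", method=method, spec=spec, coding=coding,
    )


def fit_model(data: pd.DataFrame, spec: ModelSpec, **kwargs) -> MixedModelFit:
    if spec.family == "binomial":
        return fit_glmm_binomial(data, spec, **kwargs)
    return fit_lmm(data, spec, **kwargs)


# ---------------------------------------------------------------------------
# inference


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def lrt(full: MixedModelFit, reduced: MixedModelFit) -> LRTResult:
    """Likelihood-ratio test of nested ML fits on the same data."""
    if full.method != "ML" or reduced.method != "ML":
        raise ModelError("LRT requires ML fits (REML likelihoods are not comparable)")
    if full.n_obs != reduced.n_obs:
        raise ModelError("fits are not on the same data")
    df = len(full.beta) - len(reduced.beta)
    if df < 1:
        if df == 0 and abs(full.loglik - reduced.loglik) < 1e-8:
            return LRTResult(0.0, 0, 1.0)
        raise ModelError("models are not nested (no dropped fixed effects)")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LRTResult(float(stat), int(df), float(stats.chi2.sf(stat, df)))


def _reduced_terms(terms: Sequence[str], drop: str) -> list[str]:
    return [t for t in terms if t != drop]


def termwise_lrt(
    data: pd.DataFrame, spec: ModelSpec, coding: str = "treatment", **fit_kwargs
) -> pd.DataFrame:
    """Type-II likelihood-ratio test per fixed term.

    Each main effect is tested by dropping it from a model that excludes any
    interaction containing it (respecting marginality); interactions are
    tested against the full model.
    """
    rows = []
    cache: dict = {}

    def fit_terms(terms):
        key = tuple(terms)
        if key not in cache:
            s = ModelSpec(spec.response, list(terms), spec.grouping, spec.family)
            cache[key] = fit_model(data, s, coding=coding, **fit_kwargs)
        return cache[key]

    for term in spec.fixed_terms:
        if ":" in term:
            full_terms = list(spec.fixed_terms)
        else:
            full_terms = [
                t for t in spec.fixed_terms
                if ":" not in t or term not in t.split(":")
            ]
        res = lrt(fit_terms(full_terms), fit_terms(_reduced_terms(full_terms, term)))
        rows.append({"term": term, "chisq": res.statistic, "df": res.df,
                     "p": res.p_value})
    return pd.DataFrame(rows)


def dispersion(fit: MixedModelFit, data: pd.DataFrame, aggregate: bool = False) -> float:
    """Pearson overdispersion ratio of a binomial fit.

    Sum of squared Pearson residuals at the conditional fitted values (random
    intercepts at their conditional modes), divided by the residual degrees
    of freedom n - p_fixed - n_groups. Values near 1 indicate the binomial
    variance assumption holds.

    With strictly binary rows a calibrated fit has Pearson ratio ~1 by
    construction, so extra-binomial variation from duplicated or clustered
    outcomes is invisible at the row level; ``aggregate=True`` first pools
    rows sharing identical fitted values and group into binomial cells, which
    makes such duplication show up as a ratio well above 1.
    """
    if fit.family != "binomial":
        raise ModelError("dispersion ratio is defined for the binomial fit")
    X, _, _ = build_design(data, fit.spec, fit.coding)
    y = _response(data, fit.spec)
    groups = pd.factorize(data[fit.spec.grouping])[0]
    prob = _AGQProblem(X, y, groups, max(fit.n_quad, 7))
    u_hat = prob.conditional_modes(fit.beta, fit.sigma_u2)
    reps = np.diff(np.append(prob.starts, prob.n))
    mu = special.expit(prob.X @ fit.beta + np.repeat(u_hat, reps))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    if aggregate:
        cell = pd.DataFrame({"mu": np.round(mu, 12),
                             "g": np.repeat(np.arange(prob.n_groups), reps),
                             "y": prob.y})
        agg = cell.groupby(["g", "mu"], sort=False).agg(
            successes=("y", "sum"), size=("y", "size")).reset_index()
        resid2 = ((agg["successes"] - agg["size"] * agg["mu"]) ** 2
                  / (agg["size"] * agg["mu"] * (1 - agg["mu"])))
        n_units = len(agg)
    else:
        resid2 = (prob.y - mu) ** 2 / (mu * (1 - mu))
        n_units = fit.n_obs
    df = n_units - len(fit.beta) - fit.n_groups
    if df <= 0:
        raise ModelError("non-positive residual degrees of freedom")
    return float(np.sum(resid2) / df)


@dataclass
class PhaseCI:
    phase: str
    estimate: float
    lower95: float
    upper95: float
    differs_from_control: bool


def phase_cis(
    fit: MixedModelFit,
    data: pd.DataFrame,
    phase_term: str = "phase",
    ci_method: str = "overlap",
) -> list[PhaseCI]:
    """Per-phase Wald 95% CIs, each compared against the control phase.

    The estimate for each phase is the fixed-effect linear predictor at that
    phase with all other covariates held at their sample means (link scale).
    ``ci_method="overlap"`` flags a phase whose interval does not overlap the
    control interval (the graphical comparison); ``"difference"`` flags a
    phase whose CI for the difference from control excludes zero.
    """
    if phase_term not in fit.term_cols:
        raise ModelError(f"term {phase_term!r} is not in the fitted model")
    if fit.coding != "treatment":
        raise ModelError("phase_cis requires treatment (reference) coding")
    X, _, _ = build_design(data, fit.spec, fit.coding)
    base = X.mean(axis=0)
    phase_idx = fit.term_cols[phase_term]
    base[phase_idx] = 0.0
    levels = _levels(data[phase_term])
    z = stats.norm.ppf(0.975)

    def interval(contrast):
        est = float(contrast @ fit.beta)
        se = float(np.sqrt(max(contrast @ fit.vcov_beta @ contrast, 0.0)))
        return est, est - z * se, est + z * se

    c0 = base.copy()
    ctrl = interval(c0)
    out = []
    for i, lv in enumerate(levels):
        c = base.copy()
        if i > 0:
            c[phase_idx[i - 1]] = 1.0
        est, lo, hi = interval(c)
        if i > 0 and abs(fit.beta[phase_idx[i - 1]]) > 10:
            # (quasi-)complete separation: the likelihood is flat in this
            # coefficient and its Wald interval is meaningless — report an
            # unbounded interval and never flag a difference
            out.append(PhaseCI(lv, est, -np.inf, np.inf, False))
            continue
        if lv == levels[0]:
            differs = False
        elif ci_method == "overlap":
            differs = bool(hi < ctrl[1] or lo > ctrl[2])
        elif ci_method == "difference":
            d = c - c0
            dest = float(d @ fit.beta)
            dse = float(np.sqrt(max(d @ fit.vcov_beta @ d, 0.0)))
            differs = bool(abs(dest) > z * dse)
        else:
            raise ModelError(f"unknown ci_method {ci_method!r}")
        out.append(PhaseCI(lv, est, lo, hi, differs))
    return out


def r2_nakagawa(fit: MixedModelFit, data: pd.DataFrame) -> tuple[float, float]:
    """Marginal and conditional R^2 of a mixed model.

    marginal = var_fixed / (var_fixed + sigma_u^2 + sigma_resid);
    conditional adds sigma_u^2 to the numerator. var_fixed is the population
    variance of the fixed-effect linear predictor. For the binomial-logit
    model the residual variance on the latent scale is pi^2 / 3.
    """
    X, _, _ = build_design(data, fit.spec, fit.coding)
    eta = X @ fit.beta
    var_f = float(np.var(eta))  # population variance, matching the ML sigma_e2
    resid = np.pi**2 / 3.0 if fit.family == "binomial" else fit.sigma_e2
    total = var_f + fit.sigma_u2 + resid
    if total <= 0:
        raise ModelError("degenerate model: zero total variance")
    return var_f / total, (var_f + fit.sigma_u2) / total


# ---------------------------------------------------------------------------
# control-phase design checks


def control_phase_checks(kinematics: pd.DataFrame) -> dict:
    """The control-phase models: does target position or peck order matter?

    Runs three random-intercept models on control-phase records — binomial
    grasping success, Gaussian grasping onset and Gaussian movement distance,
    each with target position, peck order and their interaction — and reports
    a Type-II LRT per term. A degenerate response (e.g. every peck a success)
    yields a warning entry instead of a fit.
    """
    required = {"target_position", "peck_order", "individual", "outcome"}
    missing = required - set(kinematics.columns)
    if missing:
        raise ModelError(f"missing column(s) {sorted(missing)}")
    ctrl = kinematics[kinematics["phase"] == "control"] \
        if "phase" in kinematics.columns else kinematics
    terms = ["target_position", "peck_order", "target_position:peck_order"]
    report: dict = {}

    succ = ctrl["outcome"].astype(str) == "success"
    if succ.nunique() < 2:
        warnings.warn("grasping success is constant in the control phase; "
                      "success model not fitted", DegenerateResponseWarning)
        report["success"] = None
    else:
        spec = ModelSpec("outcome", terms, "individual", family="binomial")
        report["success"] = termwise_lrt(ctrl, spec)

    for name, col in (("onset", "onset_s"), ("distance", "distance_cm")):
        sub = ctrl.dropna(subset=[col]) if col in ctrl.columns else pd.DataFrame()
        if len(sub) < 10 or sub[col].nunique() < 2:
            warnings.warn(f"{name} response degenerate or too sparse; skipped",
                          DegenerateResponseWarning)
            report[name] = None
            continue
        spec = ModelSpec(col, terms, "individual", family="gaussian")
        report[name] = termwise_lrt(sub, spec)
    return report
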