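"""Binomial mixed models with Gaussian-kernel temporal autocorrelation terms.

The response is the daily dyad-level binary affiliation indicator,
modelled with a logit link, an observation-effort offset, fixed test
predictors and controls, and independent Gaussian random effects
(intercepts for male, infant, dyad, group and day, plus an optional
subset of random slopes for the test predictors).

The marginal likelihood is approximated by the Laplace method: for a
candidate vector of random-effect standard deviations, the joint
posterior mode of (fixed coefficients, random effects) is found by
penalized iteratively reweighted least squares, and the log marginal
likelihood is the penalized log-likelihood at the mode minus half the
log-determinant of ``I + D^{1/2} Z'WZ D^{1/2}``.  The outer problem
(over log standard deviations) is solved by Nelder-Mead from a fixed
start, so the whole fit is deterministic given the data.

Temporal non-independence is absorbed by two autocorrelation (AC)
covariates, one keyed on the infant and one on the male: for each row
the AC value is the weighted average of the response-scale residuals of
all *other* rows sharing the key, with Gaussian weights
``exp(-dt^2 / (2 sigma^2))`` in the day lag.  Each kernel SD ``sigma``
is chosen to maximize the refitted model's log-likelihood (log-spaced
grid search then golden-section refinement), the two keys optimized
sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse
from scipy import stats
from scipy.special import expit

from nigra.errors import DataError

# canonical term structures ---------------------------------------------------

TEST_MAINS = [
    "paternity",
    "z_male_rank",
    "z_mother_rank",
    "z_mother_presence",
    "z_mother_male_affiliation",
]
TEST_TWO_WAYS = [
    "z_male_rank:paternity",
    "z_male_rank:z_mother_presence",
    "paternity:z_mother_presence",
    "z_male_rank:z_mother_male_affiliation",
    "paternity:z_mother_male_affiliation",
    "z_mother_presence:z_mother_male_affiliation",
]
TEST_THREE_WAYS = [
    "z_male_rank:paternity:z_mother_presence",
    "z_male_rank:paternity:z_mother_male_affiliation",
]
CONTROL_TERMS = [
    "infant_sex_male",
    "z_infant_age",
    "z_n_males",
    "season_sin",
    "season_cos",
    "z_tenure",
]


def full_test_terms(direction: str) -> list[str]:
    """The canonical full set of test fixed-effect terms for a direction.

    13 terms for the infant model (5 mains, 6 two-way, 2 three-way
    interactions), 14 for the male model (adds presence at conception).
    """
    terms = TEST_MAINS + TEST_TWO_WAYS + TEST_THREE_WAYS
    if direction == "male":
        terms = terms + ["conception"]
    return list(terms)


@dataclass(frozen=True)
class RandomTerm:
    """One independent random-effect block: intercept or slope by group."""

    group_col: str
    slope_col: str | None = None

    @property
    def name(self) -> str:
        return self.group_col if self.slope_col is None else (
            f"{self.slope_col}|{self.group_col}"
        )


def default_random_terms(slopes: str = "reduced") -> list[RandomTerm]:
    """Random intercepts for male, infant, dyad, group, day; plus slopes.

    ``slopes="glm"`` gives no random terms at all (a plain logistic
    fit), ``"none"`` intercepts only, ``"reduced"`` adds the male-rank
    and mother-presence slopes within infant (a desk-scale subset),
    ``"full"`` a slope for every test main within infant, male and
    dyad.
    """
    if slopes == "glm":
        return []
    terms = [RandomTerm(g) for g in ("male", "infant", "dyad", "group", "day")]
    if slopes == "none":
        return terms
    if slopes == "reduced":
        return terms + [
            RandomTerm("infant", "z_male_rank"),
            RandomTerm("infant", "z_mother_presence"),
        ]
    if slopes == "full":
        for g in ("infant", "male", "dyad"):
            for s in TEST_MAINS:
                terms.append(RandomTerm(g, s))
        return terms
    raise ValueError("slopes must be 'glm', 'none', 'reduced' or 'full'")


@dataclass
class ModelSpec:
    """Fixed/random structure of one model (full or reduced)."""

    response: str = "response"
    test_terms: list[str] = field(default_factory=list)
    control_terms: list[str] = field(default_factory=lambda: list(CONTROL_TERMS))
    ac_terms: list[str] = field(default_factory=list)  # AC covariate columns
    offset: str | None = "log_obs"
    random_terms: list[RandomTerm] = field(default_factory=list)

    @property
    def fixed_terms(self) -> list[str]:
        return self.test_terms + self.control_terms + self.ac_terms

    def null_spec(self) -> "ModelSpec":
        """Same model minus all test predictors (AC, offset, controls,
        randoms retained)."""
        return replace(self, test_terms=[])

    def drop_term(self, term: str) -> "ModelSpec":
        return replace(self, test_terms=[t for t in self.test_terms if t != term])


@dataclass
class FitResult:
    params: pd.Series
    se: pd.Series
    loglik: float
    vc: dict[str, float]  # random term name -> variance
    converged: bool
    n: int
    spec: ModelSpec
    method: str = "laplace"
    ac_sigmas: dict[str, float] = field(default_factory=dict)
    fitted_mu: np.ndarray | None = field(default=None, repr=False)
    theta: np.ndarray | None = field(default=None, repr=False)  # log-SDs

    @property
    def n_fixed(self) -> int:
        return len(self.params)

    @property
    def n_params(self) -> int:
        return len(self.params) + len(self.vc)


# design matrices -------------------------------------------------------------

def build_design(table: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + one column per term; ``a:b`` terms are products."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    for t in terms:
        parts = t.split(":")
        missing = [p for p in parts if p not in table.columns]
        if missing:
            raise DataError(f"term {t!r}: missing columns {missing}")
        col = np.ones(n)
        for p in parts:
            col = col * table[p].to_numpy(dtype=float)
        cols.append(col)
        names.append(t)
    return np.column_stack(cols), names


def build_random_design(
    table: pd.DataFrame, terms: list[RandomTerm]
) -> tuple[scipy.sparse.csr_matrix, np.ndarray, list[str]]:
    """Sparse Z and a map from each Z column to its variance-term index."""
    n = len(table)
    blocks = []
    owner = []
    names = []
    for k, term in enumerate(terms):
        codes, levels = pd.factorize(table[term.group_col], sort=True)
        vals = (
            np.ones(n)
            if term.slope_col is None
            else table[term.slope_col].to_numpy(dtype=float)
        )
        block = scipy.sparse.csr_matrix(
            (vals, (np.arange(n), codes)), shape=(n, len(levels))
        )
        blocks.append(block)
        owner.extend([k] * len(levels))
        names.append(term.name)
    if blocks:
        Z = scipy.sparse.hstack(blocks, format="csr")
    else:
        Z = scipy.sparse.csr_matrix((n, 0))
    return Z, np.array(owner, dtype=int), names


# fitting ---------------------------------------------------------------------

def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log f(y | eta) with numerically safe log(1 + e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _penalized_irls(
    y: np.ndarray,
    X: np.ndarray,
    Z: scipy.sparse.csr_matrix,
    offset: np.ndarray,
    prec: np.ndarray,  # per-Z-column prior precision (1/sigma^2)
    delta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Joint Newton over (beta, u); returns (delta, H_diag_free_H, converged).

    The second element is the (p+q)x(p+q) penalized Hessian at the
    optimum (dense), reused for the Laplace determinant and for SEs.
    """
    n, p = X.shape
    q = Z.shape[1]
    C = scipy.sparse.hstack([scipy.sparse.csr_matrix(X), Z], format="csr")
    pen = np.concatenate([np.zeros(p), prec])
    delta = np.zeros(p + q) if delta0 is None else delta0.copy()
    obj_old = -np.inf
    H = None
    converged = False
    for _ in range(max_iter):
        eta = C @ delta + offset
        mu = expit(eta)
        obj = _bernoulli_loglik(y, eta) - 0.5 * float(np.sum(pen * delta**2))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = C.T @ (y - mu) - pen * delta
        WC = C.multiply(w[:, None])
        H = (C.T @ WC).toarray()
        H[np.diag_indices_from(H)] += pen
        try:
            chol = scipy.linalg.cho_factor(H)
        except scipy.linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-8
            chol = scipy.linalg.cho_factor(H)
        step = scipy.linalg.cho_solve(chol, grad)
        # backtracking line search on the penalized objective
        t = 1.0
        for _ in range(30):
            cand = delta + t * step
            eta_c = C @ cand + offset
            obj_c = _bernoulli_loglik(y, eta_c) - 0.5 * float(
                np.sum(pen * cand**2)
            )
            if obj_c >= obj - 1e-12:
                break
            t *= 0.5
        delta = delta + t * step
        if abs(obj_c - obj_old) < tol * (1 + abs(obj_c)):
            converged = True
            break
        obj_old = obj_c
    return delta, H, converged


def _laplace_loglik(
    theta: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    Z: scipy.sparse.csr_matrix,
    offset: np.ndarray,
    owner: np.ndarray,
    warm: dict,
) -> float:
    sigma = np.exp(np.clip(theta, -5.0, 4.0))
    prec = 1.0 / sigma[owner] ** 2 if owner.size else np.zeros(0)
    delta, H, _ = _penalized_irls(
        y, X, Z, offset, prec, delta0=warm.get("delta")
    )
    warm["delta"] = delta
    p = X.shape[1]
    eta = X @ delta[:p] + Z @ delta[p:] + offset
    ll = _bernoulli_loglik(y, eta) - 0.5 * float(np.sum(prec * delta[p:] ** 2))
    if Z.shape[1]:
        # log det(I + D^{1/2} Z'WZ D^{1/2}) from the u-block of H:
        # H_u = Z'WZ + D^{-1}  =>  D^{1/2} H_u D^{1/2} = D^{1/2}Z'WZ D^{1/2} + I
        Hu = H[p:, p:].copy()
        d_half = sigma[owner]
        M = Hu * np.outer(d_half, d_half)
        M[np.diag_indices_from(M)] = M[np.diag_indices_from(M)] - d_half**2 * prec + 1.0
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf
        ll -= 0.5 * logdet
    return ll


def fit_glmm(
    table: pd.DataFrame,
    spec: ModelSpec,
    max_outer_iter: int = 200,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Fit one binomial-logit mixed model by Laplace approximation.

    With no random terms this reduces to a plain logistic regression
    (exact likelihood).  Non-convergence is flagged on the result, not
    raised.
    """
    y = table[spec.response].to_numpy(dtype=float)
    X, names = build_design(table, spec.fixed_terms)
    offset = (
        table[spec.offset].to_numpy(dtype=float)
        if spec.offset
        else np.zeros(len(table))
    )
    sds = X[:, 1:].std(axis=0) if X.shape[1] > 1 else np.array([1.0])
    if np.any(sds == 0):
        bad = [names[i + 1] for i in np.where(sds == 0)[0]]
        raise DataError(f"constant fixed-effect columns: {bad}")

    Z, owner, rnames = build_random_design(table, spec.random_terms)
    n_vc = len(spec.random_terms)

    if n_vc == 0:
        delta, H, conv = _penalized_irls(y, X, Z, offset, np.zeros(0))
        eta = X @ delta + offset
        ll = _bernoulli_loglik(y, eta)
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return FitResult(
            params=pd.Series(delta, index=names),
            se=pd.Series(se, index=names),
            loglik=ll, vc={}, converged=conv, n=len(table), spec=spec,
            fitted_mu=expit(eta),
        )

    warm: dict = {}
    if theta0 is None:
        theta0 = np.full(n_vc, np.log(0.5))
    res = scipy.optimize.minimize(
        lambda th: -_laplace_loglik(th, y, X, Z, offset, owner, warm),
        np.asarray(theta0, dtype=float),
        method="Nelder-Mead",
        options={
            "maxiter": max_outer_iter * n_vc,
            "xatol": 1e-3, "fatol": 1e-5, "adaptive": n_vc > 4,
        },
    )
    theta = np.clip(res.x, -5.0, 4.0)
    sigma = np.exp(theta)
    prec = 1.0 / sigma[owner] ** 2
    delta, H, conv_inner = _penalized_irls(y, X, Z, offset, prec, warm.get("delta"))
    ll = _laplace_loglik(theta, y, X, Z, offset, owner, warm)
    p = X.shape[1]
    cov = np.linalg.inv(H)
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    eta = X @ delta[:p] + Z @ delta[p:] + offset
    return FitResult(
        params=pd.Series(delta[:p], index=names),
        se=pd.Series(se, index=names),
        loglik=float(ll),
        vc={rn: float(s**2) for rn, s in zip(rnames, sigma)},
        converged=bool(res.success and conv_inner),
        n=len(table), spec=spec,
        fitted_mu=expit(eta),
        theta=theta,
    )


def response_residuals(
    table: pd.DataFrame, fit: FitResult, kind: str = "response"
) -> np.ndarray:
    """Residuals from a fit: ``"response"`` (y - fitted probability,
    default) or ``"working"`` ((y - mu) / (mu (1 - mu)))."""
    mu = fit.fitted_mu
    y = table[fit.spec.response].to_numpy(dtype=float)
    r = y - mu
    if kind == "working":
        return r / np.clip(mu * (1 - mu), 1e-10, None)
    if kind != "response":
        raise ValueError("kind must be 'response' or 'working'")
    return r


# AC terms --------------------------------------------------------------------

def compute_ac_term(
    days: np.ndarray,
    keys: np.ndarray,
    residuals: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Gaussian-kernel average of same-key residuals, excluding self.

    ``AC_i = sum_{j != i, key_j = key_i} w_ij r_j / sum w_ij`` with
    ``w_ij = exp(-dt_ij^2 / (2 sigma^2))``; rows with no same-key
    partner get 0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    days = np.asarray(days, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    out = np.zeros(len(days))
    order = pd.factorize(keys)[0]
    for k in np.unique(order):
        idx = np.where(order == k)[0]
        if idx.size < 2:
            continue
        d = days[idx]
        r = residuals[idx]
        w = np.exp(-((d[:, None] - d[None, :]) ** 2) / (2.0 * sigma**2))
        np.fill_diagonal(w, 0.0)
        denom = w.sum(axis=1)
        num = w @ r
        out[idx] = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
    return out


def attach_ac_column(
    table: pd.DataFrame, residuals: np.ndarray, key: str, sigma: float
) -> pd.DataFrame:
    out = table.copy()
    out[f"ac_{key}"] = compute_ac_term(
        out["day"].to_numpy(), out[key].to_numpy(), residuals, sigma
    )
    return out


@dataclass
class BandwidthResult:
    sigma: float
    loglik: float
    flat: bool  # no detectable autocorrelation (optimum at grid upper bound)


def optimize_bandwidth(
    table: pd.DataFrame,
    spec: ModelSpec,
    residuals: np.ndarray,
    key: str,
    grid: np.ndarray | None = None,
    refine_tol: float = 0.05,
    theta0: np.ndarray | None = None,
) -> BandwidthResult:
    """Choose the kernel SD for one AC key by profile likelihood.

    The model in ``spec`` (which should already include any other AC
    column in ``ac_terms``) is refitted with the candidate AC column
    added; a log-spaced grid locates the mode and golden-section search
    refines it in log space.  Deterministic.
    """
    if grid is None:
        grid = np.geomspace(1.0, 256.0, 9)
    col = f"ac_{key}"
    spec_ac = replace(spec, ac_terms=spec.ac_terms + [col])
    warm = {"theta": theta0}

    def ll_at(sigma: float) -> float:
        t = attach_ac_column(table, residuals, key, sigma)
        fit = fit_glmm(t, spec_ac, theta0=warm["theta"])
        warm["theta"] = fit.theta
        return fit.loglik

    lls = np.array([ll_at(s) for s in grid])
    best = int(np.argmax(lls))
    if best == len(grid) - 1:
        return BandwidthResult(float(grid[best]), float(lls[best]), flat=True)
    lo = np.log(grid[max(best - 1, 0)])
    hi = np.log(grid[min(best + 1, len(grid) - 1)])
    opt = scipy.optimize.minimize_scalar(
        lambda t: -ll_at(float(np.exp(t))),
        bounds=(lo, hi), method="bounded",
        options={"xatol": refine_tol},
    )
    sigma = float(np.exp(opt.x))
    ll = float(-opt.fun)
    if lls[best] > ll:  # keep the grid point if refinement lost ground
        sigma, ll = float(grid[best]), float(lls[best])
    return BandwidthResult(sigma, ll, flat=False)


def fit_with_ac(
    table: pd.DataFrame,
    spec: ModelSpec,
    keys: tuple[str, ...] = ("infant", "male"),
    grid: np.ndarray | None = None,
) -> tuple[FitResult, pd.DataFrame]:
    """Full AC workflow: base fit, sequential bandwidth optimization,
    final fit with both AC covariates.

    Returns ``(final_fit, table_with_ac_columns)``; the fit records the
    chosen kernel SDs in ``ac_sigmas``.
    """
    base = fit_glmm(table, spec)
    resid = response_residuals(table, base)
    work = table
    cur_spec = spec
    sigmas: dict[str, float] = {}
    theta = base.theta
    for key in keys:
        bw = optimize_bandwidth(work, cur_spec, resid, key, grid=grid, theta0=theta)
        work = attach_ac_column(work, resid, key, bw.sigma)
        cur_spec = replace(cur_spec, ac_terms=cur_spec.ac_terms + [f"ac_{key}"])
        sigmas[key] = bw.sigma
    final = fit_glmm(work, cur_spec, theta0=theta)
    final.ac_sigmas = sigmas
    return final, work


# inference -------------------------------------------------------------------

def lrt(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood ratio test of nested fits: (chi2, df, p).

    chi2 is floored at 0; df is the difference in parameter counts
    (fixed + variance parameters).
    """
    df = full.n_params - reduced.n_params
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        return chi2, 0, 1.0
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def full_vs_null(table: pd.DataFrame, spec: ModelSpec) -> tuple[float, int, float]:
    full = fit_glmm(table, spec)
    null = fit_glmm(table, spec.null_spec())
    return lrt(full, null)


def prune_interactions(
    table: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Hierarchical backward pruning of interaction terms.

    Three-way interactions are LRT-tested (model without the term vs
    with) and non-significant ones removed, then surviving two-ways
    likewise, in declaration order within each tier.  Two-way terms
    contained in a retained three-way are never tested or removed, so
    the final model is always hierarchical.
    """
    current = spec
    log_rows = []
    cur_fit = fit_glmm(table, current)
    for tier in (3, 2):
        for term in [t for t in list(current.test_terms) if t.count(":") == tier - 1]:
            if tier == 2 and _protected(term, current.test_terms):
                log_rows.append((term, np.nan, 0, np.nan, "kept_protected"))
                continue
            reduced_spec = current.drop_term(term)
            red_fit = fit_glmm(table, reduced_spec, theta0=cur_fit.theta)
            chi2, df, p = lrt(cur_fit, red_fit)
            if p > alpha:
                current = reduced_spec
                cur_fit = red_fit
                log_rows.append((term, chi2, df, p, "removed"))
            else:
                log_rows.append((term, chi2, df, p, "kept"))
    log = pd.DataFrame(
        log_rows, columns=["term", "chi2", "df", "p", "action"]
    )
    return current, log


def _protected(two_way: str, terms: list[str]) -> bool:
    parts = set(two_way.split(":"))
    return any(
        parts <= set(t.split(":")) for t in terms if t.count(":") == 2
    )


def vif(table: pd.DataFrame, terms: list[str]) -> pd.Series:
    """Variance inflation factors among main-effect predictors.

    ``VIF_k = 1 / (1 - R^2_k)`` with ``R^2_k`` from regressing column k
    on the other columns (plus an intercept).  Interaction terms are
    excluded by the caller.  Perfect collinearity raises.
    """
    mains = [t for t in terms if ":" not in t]
    if len(mains) < 2:
        raise DataError("need >= 2 main-effect columns for VIF")
    Xf = np.column_stack([table[t].to_numpy(dtype=float) for t in mains])
    n = len(table)
    out = {}
    for k, t in enumerate(mains):
        yk = Xf[:, k]
        others = np.column_stack(
            [np.ones(n)] + [Xf[:, j] for j in range(Xf.shape[1]) if j != k]
        )
        beta, *_ = np.linalg.lstsq(others, yk, rcond=None)
        resid = yk - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yk - yk.mean()) ** 2))
        if ss_tot == 0:
            raise DataError(f"predictor {t!r} is constant")
        r2 = 1.0 - ss_res / ss_tot
        if r2 > 1 - 1e-10:
            raise DataError(f"perfect collinearity involving {t!r}")
        out[t] = 1.0 / (1.0 - r2)
    return pd.Series(out)


def stability_check(
    table: pd.DataFrame,
    spec: ModelSpec,
    fit: FitResult | None = None,
    group_cols: tuple[str, ...] = ("infant", "male", "group"),
) -> pd.DataFrame:
    """Leave-one-level-out refits of the final model.

    For every level of every random-effect grouping column the model is
    refitted on the data without that level's rows; the output has one
    row per excluded level with the maximum absolute change over the
    fixed estimates.
    """
    if fit is None:
        fit = fit_glmm(table, spec)
    base = fit.params
    rows = []
    for col in group_cols:
        if col not in table.columns:
            continue
        for level in sorted(table[col].astype(str).unique()):
            sub = table[table[col].astype(str) != level]
            if sub[spec.response].nunique() < 2:
                continue
            try:
                refit = fit_glmm(sub, spec)
            except DataError:
                continue
            common = base.index.intersection(refit.params.index)
            delta = (refit.params[common] - base[common]).abs()
            rows.append((col, level, float(delta.max()), delta.idxmax()))
    return pd.DataFrame(
        rows, columns=["group_col", "level", "max_abs_delta", "worst_term"]
    )
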