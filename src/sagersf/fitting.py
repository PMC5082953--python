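"""Mixed-effects logistic RSF fitting and AICc multimodel inference.

The core model is a used-available binomial GLM with a logit link and a
Gaussian random intercept per animal (the shared availability sample forms one
reserved pseudo-group).  The marginal likelihood integrates the intercept out
by adaptive Gauss-Hermite quadrature: per group the integrand mode is located
by Newton steps, the quadrature grid is centered and scaled there, and 21
nodes evaluate the integral - accurate to well below 1e-4 in log-likelihood
against dense numerical integration.

Model-set machinery implements all-subsets enumeration, small-sample corrected
AIC, Akaike weights, and the 95% cumulative-weight confidence set with
renormalized weights, matching standard information-theoretic practice.

Covariates are standardized internally for optimization; coefficients, their
standard errors and Wald intervals are reported on both the standardized and
the original scale (the standardized fit is the exact reparameterization, so
``standardized_fit`` and the internal scaling agree to optimizer precision).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .layers import AVAILABLE_GROUP

DEFAULT_THRESHOLD = 0.65
DEFAULT_MASS = 0.95
ALL_SUBSETS_GUARD = 12


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation on a named covariate."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the scipy trace."""


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    pairwise_r: pd.DataFrame
    threshold: float
    dropped: list[tuple[str, str, float]]  # (variable, kept partner, r)
    retained: list[str]


def pearson_screen(table: pd.DataFrame, covariates: list[str],
                   threshold: float = DEFAULT_THRESHOLD,
                   priority: list[str] | None = None) -> ScreeningReport:
    """Drop the lower-priority member of every covariate pair with |r| > threshold.

    Variables are admitted in priority order; a candidate is dropped when its
    Pearson correlation with any already-retained variable exceeds the
    threshold in absolute value, so the outcome depends only on the priority
    list, never on column order.  Constant columns are dropped with a warning.
    """
    priority = list(priority) if priority is not None else list(covariates)
    missing = [v for v in covariates if v not in priority]
    priority = priority + missing  # unprioritized variables go last
    cols = [v for v in priority if v in covariates]
    sub = table[cols].astype(float)
    const = [c for c in cols if sub[c].std(ddof=0) == 0]
    if const:
        warnings.warn(f"constant covariates dropped before screening: {const}")
        cols = [c for c in cols if c not in const]
        sub = sub[cols]
    r = sub.corr(method="pearson")
    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for var in cols:
        partner = None
        for kept in retained:
            if abs(r.loc[var, kept]) > threshold:
                partner = kept
                break
        if partner is None:
            retained.append(var)
        else:
            dropped.append((var, partner, float(r.loc[var, partner])))
    dropped = [(v, "", np.nan) for v in const] + dropped
    return ScreeningReport(pairwise_r=r, threshold=threshold, dropped=dropped,
                           retained=retained)


# ---------------------------------------------------------------------------
# information criteria and weights
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2*loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs) -> tuple[np.ndarray, np.ndarray]:
    """(weights, deltas) from a list of AICc values."""
    a = np.asarray(list(aiccs), dtype=float)
    if a.size == 0:
        raise ValueError("empty model list")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum(), delta


def all_subsets(variables: list[str], guard: int = ALL_SUBSETS_GUARD) -> list[tuple[str, ...]]:
    """All 2^p covariate subsets (including the intercept-only model)."""
    variables = list(variables)
    if len(variables) > guard:
        raise ValueError(
            f"{len(variables)} variables would enumerate {2 ** len(variables)} models; "
            "pass an explicit model list instead")
    out = []
    for size in range(len(variables) + 1):
        out.extend(itertools.combinations(variables, size))
    return out


# ---------------------------------------------------------------------------
# mixed logit via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def assign_available_groups(table: pd.DataFrame, mode: str = "random_bird",
                            seed: int = 0, response: str = "response",
                            bird: str = "bird_id") -> pd.DataFrame:
    """Add the random-effect ``group`` column for a used-available table.

    Used rows always group by bird.  For available rows the default
    ``random_bird`` mode apportions the shared seasonal pool uniformly at
    random (seeded) among the season's birds, which keeps a single
    availability sample while leaving the intercept variance identifiable.
    ``pooled`` keeps every available row in one reserved pseudo-group; note
    that grouping is then perfectly aligned with the response, the marginal
    likelihood is monotone in sigma_b, and the fit degenerates - the mode
    exists only for sensitivity comparisons.
    """
    out = table.copy()
    used = out[response] == 1
    out["group"] = out[bird].astype(str)
    if mode == "random_bird":
        birds = out.loc[used, bird].astype(str).unique()
        if len(birds) == 0:
            raise ValueError("no used rows to take bird ids from")
        # salted stream: the assignment must stay independent of any other
        # stage seeded with the same integer, or the bird labels correlate
        # with the availability draw and fabricate group-level structure
        rng = np.random.default_rng([seed, 0x5AB1E])
        n_av = int((~used).sum())
        out.loc[~used, "group"] = rng.choice(birds, size=n_av)
    elif mode == "pooled":
        out.loc[~used, "group"] = AVAILABLE_GROUP
    else:
        raise ValueError(f"unknown availability grouping mode '{mode}'")
    return out

LOG_SIGMA_FLOOR = -7.0  # sigma_b ~ 9e-4: numerically the fixed-effects model


def _prepare(table: pd.DataFrame, covariates, response: str, group: str):
    y = table[response].to_numpy(dtype=float)
    if not set(np.unique(y)).issubset({0.0, 1.0}):
        raise ValueError("response must be coded 1 used / 0 available")
    X = np.column_stack([np.ones(len(table))] +
                        [table[c].to_numpy(dtype=float) for c in covariates])
    g_codes, g_labels = pd.factorize(table[group])
    return y, X, g_codes, len(g_labels)


class _MarginalLoglik:
    """Marginal log-likelihood and score for (beta, log sigma_b)."""

    def __init__(self, y, X, groups, n_groups, n_quad=21):
        self.y, self.X, self.g, self.G = y, X, groups, n_groups
        z, w = np.polynomial.hermite.hermgauss(n_quad)
        self.z, self.logw = z, np.log(w)
        self.ones = np.ones(len(y))

    def _group_sum(self, vals):
        return np.bincount(self.g, weights=vals, minlength=self.G)

    def _modes(self, eta0, sigma):
        """Per-group Newton maximization of the integrand exponent over b."""
        y, g = self.y, self.g
        b = np.zeros(self.G)
        inv_s2 = 1.0 / sigma ** 2
        for _ in range(50):
            eta = eta0 + b[g]
            p = special.expit(eta)
            grad = self._group_sum(y - p) - b * inv_s2
            hess = -self._group_sum(p * (1 - p)) - inv_s2
            step = np.clip(grad / -hess, -4.0, 4.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = eta0 + b[g]
        p = special.expit(eta)
        hess = -self._group_sum(p * (1 - p)) - inv_s2
        return b, np.sqrt(-1.0 / hess)

    def value_and_grad(self, params):
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        y, X, g = self.y, self.X, self.g
        eta0 = X @ beta
        bhat, tau = self._modes(eta0, sigma)
        # adaptive nodes b_gk = bhat_g + sqrt(2) tau_g z_k
        B = bhat[:, None] + np.sqrt(2.0) * tau[:, None] * self.z[None, :]  # (G, K)
        eta = eta0[:, None] + B[g, :]                                      # (n, K)
        # Bernoulli loglik per row/node, summed within group
        row_ll = y[:, None] * eta - np.logaddexp(0.0, eta)
        ll_gk = np.vstack([self._group_sum(row_ll[:, k]) for k in range(len(self.z))]).T
        h_gk = ll_gk - 0.5 * (B / sigma) ** 2                              # (G, K)
        log_terms = self.logw[None, :] + self.z[None, :] ** 2 + h_gk
        m = log_terms.max(axis=1, keepdims=True)
        S = np.exp(log_terms - m)
        ssum = S.sum(axis=1)
        log_Lg = (np.log(np.sqrt(2.0) * tau) - np.log(sigma * np.sqrt(2.0 * np.pi))
                  + m[:, 0] + np.log(ssum))
        loglik = float(log_Lg.sum())
        # score via posterior node weights
        pi = S / ssum[:, None]                                             # (G, K)
        p = special.expit(eta)                                             # (n, K)
        pbar = np.einsum("nk,nk->n", pi[g, :], p)
        grad_beta = X.T @ (y - pbar)
        grad_logsig = float(np.sum(pi * ((B / sigma) ** 2 - 1.0)))
        return loglik, np.append(grad_beta, grad_logsig)

    def value(self, params):
        return self.value_and_grad(params)[0]


def mixed_logit_loglik(table: pd.DataFrame, covariates, beta, sigma_b,
                       response: str = "response", group: str = "group",
                       n_quad: int = 21) -> float:
    """Marginal log-likelihood of a mixed logit at given raw-scale parameters.

    ``beta`` includes the intercept first, then one coefficient per covariate.
    """
    y, X, g, G = _prepare(table, covariates, response, group)
    ml = _MarginalLoglik(y, X, g, G, n_quad=n_quad)
    log_sigma = np.log(max(sigma_b, np.exp(LOG_SIGMA_FLOOR)))
    return ml.value(np.append(np.asarray(beta, dtype=float), log_sigma))


@dataclass
class FittedModel:
    """One mixed-logit fit with Wald inference and AICc bookkeeping."""

    season: str | None
    covariates: list[str]
    beta: pd.Series            # raw scale, index: intercept + covariates
    se: pd.Series
    lci: pd.Series
    uci: pd.Series
    beta_std: pd.Series        # coefficients for centered/scaled covariates
    se_std: pd.Series
    lci_std: pd.Series
    uci_std: pd.Series
    sigma_b: float
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool = True
    n_iter: int = 0

    @property
    def formula(self) -> str:
        return "1" if not self.covariates else " + ".join(self.covariates)

    def odds_ratios(self) -> pd.DataFrame:
        return odds_ratios(self)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: standardized and unstandardized with odds ratios."""
        tab = pd.DataFrame({
            "beta_std": self.beta_std, "se_std": self.se_std,
            "lci_std": self.lci_std, "uci_std": self.uci_std,
            "beta": self.beta, "se": self.se, "lci": self.lci, "uci": self.uci,
        })
        orat = odds_ratios(self)
        tab["odds_ratio"] = orat["odds_ratio"]
        return tab

    def predict_eta(self, table: pd.DataFrame) -> np.ndarray:
        """Fixed-effects linear predictor (random intercept at its mean, 0)."""
        eta = np.full(len(table), self.beta["intercept"])
        for c in self.covariates:
            eta = eta + self.beta[c] * table[c].to_numpy(dtype=float)
        return eta

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Relative probability of presence: logistic of the linear predictor."""
        return special.expit(self.predict_eta(table))


def fit_mixed_logit(table: pd.DataFrame, covariates, season: str | None = None,
                    response: str = "response", group: str = "group",
                    n_quad: int = 21, max_iter: int = 200,
                    start_sigma: float = 0.3) -> FittedModel:
    """Fit the used-available mixed logit for one covariate subset.

    Optimizes (beta, log sigma_b) by L-BFGS-B on internally standardized
    covariates, starting from the fixed-effects logistic fit; standard errors
    come from the inverse observed information (finite differences of the
    analytic score), mapped back to the raw covariate scale.
    """
    covariates = list(covariates)
    y, X_raw, g, G = _prepare(table, covariates, response, group)
    n, p = len(y), len(covariates)

    mu = X_raw[:, 1:].mean(axis=0) if p else np.empty(0)
    sd = X_raw[:, 1:].std(axis=0, ddof=0) if p else np.empty(0)
    zero_var = [covariates[j] for j in range(p) if sd[j] == 0]
    if zero_var:
        raise ValueError(f"zero-variance covariates: {zero_var}")
    X = X_raw.copy()
    if p:
        X[:, 1:] = (X_raw[:, 1:] - mu) / sd

    # fixed-effects start
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fe = sm.Logit(y, X).fit(method="lbfgs", maxiter=200, disp=0)
            beta0 = np.asarray(fe.params, dtype=float)
        except Exception:
            beta0 = np.zeros(p + 1)
    if not np.all(np.isfinite(beta0)):
        beta0 = np.zeros(p + 1)

    ml = _MarginalLoglik(y, X, g, G, n_quad=n_quad)

    def negloglik(params):
        val, grad = ml.value_and_grad(params)
        if not np.isfinite(val):
            return np.inf, np.zeros_like(params)
        return -val, -grad

    x0 = np.append(beta0, np.log(start_sigma))
    bounds = [(None, None)] * (p + 1) + [(LOG_SIGMA_FLOOR, 3.0)]
    res = optimize.minimize(negloglik, x0, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7})
    if not res.success:
        pg = np.asarray(res.jac, dtype=float).copy()
        # ignore gradient components pressing against an active sigma bound
        if res.x[-1] <= LOG_SIGMA_FLOOR + 1e-9 and pg[-1] > 0:
            pg[-1] = 0.0
        if res.x[-1] >= 3.0 - 1e-9 and pg[-1] < 0:
            pg[-1] = 0.0
        if np.linalg.norm(pg, np.inf) > 1e-3 * max(1.0, abs(res.fun)):
            raise ConvergenceError(
                f"mixed-logit optimizer did not converge: {res.message}\n{res}")
    beta_std_hat = res.x[:-1]
    log_sigma_hat = res.x[-1]
    sigma_b = float(np.exp(log_sigma_hat))
    big = np.abs(beta_std_hat[1:]) > 15
    if np.any(big):
        bad = [covariates[j] for j in np.nonzero(big)[0]]
        raise SeparationError(f"complete separation suspected on: {bad}")
    loglik = float(-res.fun)

    # observed information by central differences of the analytic score
    at_floor = log_sigma_hat <= LOG_SIGMA_FLOOR + 1e-6
    n_free = p + 1 if at_floor else p + 2
    H = np.zeros((n_free, n_free))
    for j in range(n_free):
        h = 1e-5 * max(1.0, abs(res.x[j]))
        xp, xm = res.x.copy(), res.x.copy()
        xp[j] += h
        xm[j] -= h
        gp = ml.value_and_grad(xp)[1]
        gm = ml.value_and_grad(xm)[1]
        H[j, :] = -(gp[:n_free] - gm[:n_free]) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov_std = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_std = np.linalg.pinv(H)
    cov_bb = cov_std[:p + 1, :p + 1]

    # map standardized estimates back to the raw covariate scale
    A = np.eye(p + 1)
    for j in range(p):
        A[0, j + 1] = -mu[j] / sd[j]
        A[j + 1, j + 1] = 1.0 / sd[j]
    beta_raw = A @ beta_std_hat
    cov_raw = A @ cov_bb @ A.T

    names = ["intercept"] + covariates
    se_std = np.sqrt(np.clip(np.diag(cov_bb), 0, None))
    se_raw = np.sqrt(np.clip(np.diag(cov_raw), 0, None))
    z = 1.96

    def series(v):
        return pd.Series(np.asarray(v, dtype=float), index=names)

    k = 1 + p + 1  # intercept + fixed effects + variance component
    return FittedModel(
        season=season, covariates=covariates,
        beta=series(beta_raw), se=series(se_raw),
        lci=series(beta_raw - z * se_raw), uci=series(beta_raw + z * se_raw),
        beta_std=series(beta_std_hat), se_std=series(se_std),
        lci_std=series(beta_std_hat - z * se_std), uci_std=series(beta_std_hat + z * se_std),
        sigma_b=sigma_b, loglik=loglik, k=k, n=n, aicc=aicc(loglik, k, n),
        converged=bool(res.success), n_iter=int(res.nit),
    )


def standardized_fit(table: pd.DataFrame, covariates, **kwargs) -> FittedModel:
    """Refit on explicitly centered/scaled covariates (mean 0, SD 1 over all
    rows, used and available); the raw-scale output of this fit IS the
    standardized coefficient table."""
    covariates = list(covariates)
    tab = table.copy()
    for c in covariates:
        v = tab[c].astype(float)
        s = v.std(ddof=0)
        if s == 0:
            raise ValueError(f"zero-variance covariate: {c}")
        tab[c] = (v - v.mean()) / s
    return fit_mixed_logit(tab, covariates, **kwargs)


def odds_ratios(fit: FittedModel) -> pd.DataFrame:
    """exp(beta) with exponentiated Wald bounds, per covariate."""
    idx = fit.covariates
    return pd.DataFrame({
        "odds_ratio": np.exp(fit.beta[idx]),
        "or_lci": np.exp(fit.lci[idx]),
        "or_uci": np.exp(fit.uci[idx]),
    })


# ---------------------------------------------------------------------------
# model sets
# ---------------------------------------------------------------------------

@dataclass
class ModelSet:
    """All fitted subsets with AICc ranking, weights and the 95% set."""

    models: list[FittedModel]
    table: pd.DataFrame = field(default=None)
    mass: float = DEFAULT_MASS

    def __post_init__(self):
        if self.table is None:
            self._build()

    def _build(self):
        order = np.argsort([m.aicc for m in self.models], kind="stable")
        self.models = [self.models[i] for i in order]
        a = [m.aicc for m in self.models]
        w, delta = akaike_weights(a)
        self.table = pd.DataFrame({
            "formula": [m.formula for m in self.models],
            "k": [m.k for m in self.models],
            "aicc": a, "delta": delta, "weight": w,
        })
        flags, renorm = confidence_flags(w, self.mass)
        self.table["in_confidence_set"] = flags
        self.table["weight_renormalized"] = renorm

    @property
    def top(self) -> FittedModel:
        return self.models[0]

    def confidence_models(self) -> list[tuple[FittedModel, float]]:
        """(model, renormalized weight) pairs over the 95% set."""
        sel = self.table["in_confidence_set"].to_numpy()
        wr = self.table["weight_renormalized"].to_numpy()
        return [(m, float(wr[i])) for i, m in enumerate(self.models) if sel[i]]


def confidence_flags(weights, mass: float = DEFAULT_MASS):
    """Flags and renormalized weights for the smallest cumulative-weight set.

    Models are taken in decreasing weight order until the cumulative weight
    reaches ``mass`` (inclusive on ties at the boundary); renormalized weights
    sum to 1 over the selected set and are 0 elsewhere.
    """
    w = np.asarray(weights, dtype=float)
    order = np.argsort(-w, kind="stable")
    cum = np.cumsum(w[order])
    # inclusive on exact ties: a prefix reaching the mass exactly qualifies
    cutoff = int(np.searchsorted(cum, mass - 1e-12)) + 1
    sel = np.zeros(len(w), dtype=bool)
    sel[order[:cutoff]] = True
    renorm = np.where(sel, w, 0.0)
    renorm = renorm / renorm.sum()
    return sel, renorm


def confidence_set(model_set: ModelSet, mass: float = DEFAULT_MASS) -> ModelSet:
    """Re-flag a model set at a different cumulative-weight mass."""
    return ModelSet(models=model_set.models, table=None, mass=mass)


def fit_all_subsets(table: pd.DataFrame, variables, season: str | None = None,
                    guard: int = ALL_SUBSETS_GUARD, **kwargs) -> ModelSet:
    """Fit every covariate subset and rank by AICc."""
    fits = []
    for spec in all_subsets(list(variables), guard=guard):
        fits.append(fit_mixed_logit(table, list(spec), season=season, **kwargs))
    return ModelSet(models=fits)
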