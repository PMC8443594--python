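"""Lognormal double-hurdle models with group random intercepts.

The first hurdle models the decision to spray at all,

    P(y = 0 | x) = 1 - Phi(x'gamma),

as a probit with a random intercept u_g ~ N(0, tau1^2) on the grouping
(default farm-by-crop-family), integrated out by Gauss-Hermite quadrature.
The second hurdle models the amount sprayed on fields with positive use,

    log(y) | x, y > 0 ~ Normal(x'beta, sigma^2),

as a linear mixed model with its own group intercept v_g ~ N(0, tau2^2),
fitted by maximum likelihood.  Inference uses cluster-robust sandwich
variances at the same grouping (heteroskedasticity-robust = singleton
clusters).  Reported effects are the discrete-change average marginal effect
of the organic indicator from hurdle one and the semi-elasticity
100(e^beta - 1) from hurdle two, both with delta-method standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, roots_hermite
from scipy.stats import norm

from orgfield.config import ConfigurationError

Z975 = 1.959963984540054


class SeparationError(RuntimeError):
    """Perfect separation: the binary outcome is constant (or separable)."""


@dataclass
class HurdleSpec:
    """What to fit and how.

    ``grouping`` names the random-intercept/cluster variable construction:
    ``farm_family`` (permit x crop family) or ``year``.  ``vcov`` selects
    cluster-robust (at the grouping) or heteroskedasticity-robust standard
    errors.  ``tau2`` fixes the random-intercept variance when not None
    (0 collapses to plain probit / OLS).
    """

    outcome: str = "product"
    covariates: tuple[str, ...] = ("organic", "log_area", "log_farm", "storie")
    grouping: str = "farm_family"
    vcov: str = "cluster"  # "cluster" | "hc"
    log_sizes: bool = True
    alpha: float = 0.05
    n_nodes: int = 20
    tol: float = 1e-10
    tau2: float | None = None  # None = estimate
    drop_imputed_soil: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_nodes < 4:
            raise ConfigurationError("need at least 4 quadrature nodes")


@dataclass
class FitResult:
    """One hurdle's estimate: coefficients, variances, fit statistics."""

    params: np.ndarray
    names: list[str]
    vcov_model: np.ndarray
    vcov_cluster: np.ndarray
    sigma2: float | None
    tau2: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    scores: np.ndarray | None = None  # per-group score contributions

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_cluster)[: len(self.params)])

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self._k

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_obs) * self._k

    @property
    def _k(self) -> int:
        extra = (1 if self.sigma2 is not None else 0) + (1 if self.tau2 > 0 else 0)
        return len(self.params) + extra

    def coef(self, name: str) -> tuple[float, float]:
        j = self.names.index(name)
        return float(self.params[j]), float(np.sqrt(self.vcov_cluster[j, j]))


@dataclass
class EffectEstimate:
    kind: str  # "AME" | "semi-elasticity" | "elasticity"
    target: str
    estimate: float
    se: float

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - Z975 * self.se, self.estimate + Z975 * self.se)


@dataclass
class HurdleFit:
    h1: FitResult
    h2: FitResult
    ame: "EffectEstimate"
    semi: "EffectEstimate"
    outcome: str
    dropped: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def _prepare(data: pd.DataFrame, spec: HurdleSpec):
    """Build design matrix, outcome columns and group codes; count drops."""
    df = data.copy()
    dropped = {}
    if spec.grouping == "farm_family" or "family" in spec.covariates:
        n0 = len(df)
        df = df[df.family.notna()]
        dropped["missing_family"] = n0 - len(df)
    n0 = len(df)
    df = df[df.storie.notna()]
    if spec.drop_imputed_soil and "storie_imputed" in df.columns:
        df = df[~df.storie_imputed.astype(bool)]
    dropped["missing_soil"] = n0 - len(df)

    if spec.grouping == "farm_family":
        group = df.permit.astype(str) + "|" + df.family.astype(str)
    elif spec.grouping == "year":
        group = df.year.astype(str)
    elif spec.grouping in df.columns:
        group = df[spec.grouping].astype(str)
    else:
        raise ConfigurationError(f"unknown grouping {spec.grouping!r}")
    codes, _ = pd.factorize(group, sort=True)

    cols = [np.ones(len(df))]
    names = ["const"]
    for c in spec.covariates:
        if c == "organic":
            cols.append(df.organic.to_numpy(dtype=float))
        elif c == "log_area":
            cols.append(np.log(df.area_adj_ha.to_numpy(dtype=float)) if spec.log_sizes
                        else df.area_adj_ha.to_numpy(dtype=float))
        elif c == "log_farm":
            cols.append(np.log(df.farm_size_ha.to_numpy(dtype=float)) if spec.log_sizes
                        else df.farm_size_ha.to_numpy(dtype=float))
        elif c in df.columns:
            cols.append(df[c].to_numpy(dtype=float))
        else:
            raise ConfigurationError(f"covariate {c!r} not found")
        names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                bad.append(names[j])
        raise np.linalg.LinAlgError(f"singular design matrix; collinear columns: {bad}")
    return df, X, names, codes, dropped


def _sorted_groups(codes: np.ndarray):
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_codes) != 0])
    return order, starts


# ---------------------------------------------------------------------------
# Hurdle 1: random-intercept probit via Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

class ProbitRE:
    """Maximum-likelihood probit with a group random intercept.

    The group intercept is integrated out with an ``n_nodes``-point
    Gauss-Hermite rule; with ``tau`` fixed at zero the likelihood reduces
    exactly to the plain probit.  Scores are analytic; the Hessian is a
    central finite difference of the score, and a Newton polish after L-BFGS
    drives the gradient to ~1e-10 so closed-form identities hold tightly.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                 n_nodes: int = 20):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.codes = np.asarray(codes)
        order, starts = _sorted_groups(self.codes)
        self.order, self.starts = order, starts
        self.n_groups = len(starts)
        nodes, weights = roots_hermite(n_nodes)
        self.nodes = nodes * np.sqrt(2.0)  # standard-normal scaling
        self.logw = np.log(weights / np.sqrt(np.pi))
        self.sign = 2.0 * self.y - 1.0

    # -- likelihood pieces ---------------------------------------------------
    def _group_loglik(self, gamma: np.ndarray, tau: float) -> np.ndarray:
        eta = self.X @ gamma
        s = self.sign[self.order]
        z = s[:, None] * (eta[self.order][:, None] + tau * self.nodes[None, :])
        lcdf = log_ndtr(z)
        group_l = np.add.reduceat(lcdf, self.starts, axis=0)  # G x K
        m = group_l.max(axis=1, keepdims=True)
        return (m[:, 0] + np.log(np.exp(group_l - m + self.logw[None, :]).sum(axis=1)))

    def loglik(self, params: np.ndarray, tau: float | None = None) -> float:
        gamma, t = self._unpack(params, tau)
        return float(self._group_loglik(gamma, t).sum())

    def group_scores(self, params: np.ndarray, tau: float | None = None,
                     per_obs: bool = False) -> np.ndarray:
        """Analytic score contributions: per group (G x p) or, with
        ``per_obs``, the within-group summands (n x p, sorted group order),
        which sum exactly to the group scores and reduce to the classic
        per-observation probit scores when tau = 0."""
        gamma, t = self._unpack(params, tau)
        free_tau = tau is None
        eta = self.X @ gamma
        s = self.sign[self.order]
        Xs = self.X[self.order]
        z = s[:, None] * (eta[self.order][:, None] + t * self.nodes[None, :])
        lcdf = log_ndtr(z)
        lam = s[:, None] * np.exp(norm.logpdf(z) - lcdf)  # d/d eta of log Phi
        group_l = np.add.reduceat(lcdf, self.starts, axis=0) + self.logw[None, :]
        m = group_l.max(axis=1, keepdims=True)
        wpost = np.exp(group_l - m)
        wpost /= wpost.sum(axis=1, keepdims=True)  # G x K posterior node weights
        obs_group = np.repeat(np.arange(self.n_groups),
                              np.diff(np.r_[self.starts, len(self.y)]))
        a = (wpost[obs_group] * lam).sum(axis=1)  # per-obs weight for gamma score
        if per_obs:
            S = np.empty((len(self.y), len(gamma) + (1 if free_tau else 0)))
            S[:, : len(gamma)] = a[:, None] * Xs
            if free_tau:
                S[:, -1] = (wpost[obs_group] * lam * self.nodes[None, :]).sum(axis=1)
            return S
        Sg = np.empty((self.n_groups, len(gamma) + (1 if free_tau else 0)))
        Sg[:, : len(gamma)] = np.add.reduceat(a[:, None] * Xs, self.starts, axis=0)
        if free_tau:
            b = (wpost[obs_group] * lam * self.nodes[None, :]).sum(axis=1)
            Sg[:, -1] = np.add.reduceat(b, self.starts)
        return Sg

    def _unpack(self, params: np.ndarray, tau: float | None):
        if tau is None:
            return params[:-1], max(float(params[-1]), 0.0)
        return params, float(tau)

    # -- fitting ---------------------------------------------------------------
    def fit(self, tau2: float | None = None, tol: float = 1e-10) -> dict:
        y, X = self.y, self.X
        if y.min() == y.max():
            raise SeparationError("binary outcome is constant; probit is not identified")
        p = X.shape[1]
        # plain-probit start via a few ad-hoc Newton steps
        gamma0 = np.zeros(p)
        fixed_tau = None if tau2 is None else float(np.sqrt(tau2))

        if tau2 is None:
            theta0 = np.r_[gamma0, 0.5]
        else:
            theta0 = gamma0

        def nll(th):
            return -self.loglik(th, fixed_tau)

        def grad(th):
            return -self.group_scores(th, fixed_tau).sum(axis=0)

        bounds = None
        if tau2 is None:
            bounds = [(None, None)] * p + [(0.0, None)]
        res = optimize.minimize(nll, theta0, jac=grad, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9})
        theta = res.x
        theta, polished = self._newton_polish(theta, fixed_tau, tol)
        gamma, t = self._unpack(theta, fixed_tau)
        if tau2 is None and abs(theta[-1]) < 1e-6:
            # boundary: re-polish gamma with tau pinned at zero
            g2, _ = self._newton_polish(gamma.copy(), 0.0, tol)
            theta = np.r_[g2, 0.0]
            gamma, t = g2, 0.0
        ll = self.loglik(theta, fixed_tau)
        if not np.isfinite(ll):
            raise SeparationError("likelihood diverged; outcome may be separable")
        H = self._numeric_hessian(theta, fixed_tau)
        return {
            "gamma": gamma, "tau": t, "theta": theta, "fixed_tau": fixed_tau,
            "loglik": ll, "hessian": H, "converged": bool(res.success or polished),
        }

    def _newton_polish(self, theta: np.ndarray, fixed_tau: float | None,
                       tol: float, max_iter: int = 25):
        ok = False
        for _ in range(max_iter):
            g = self.group_scores(theta, fixed_tau).sum(axis=0)
            if np.max(np.abs(g)) < tol:
                ok = True
                break
            H = self._numeric_hessian(theta, fixed_tau)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            ll0 = self.loglik(theta, fixed_tau)
            scale = 1.0
            while scale > 1e-4:
                cand = theta + scale * step
                if fixed_tau is None:
                    cand[-1] = max(cand[-1], 0.0)
                if self.loglik(cand, fixed_tau) >= ll0 - 1e-12:
                    theta = cand
                    break
                scale /= 2.0
            else:
                break
        return theta, ok

    def _numeric_hessian(self, theta: np.ndarray, fixed_tau: float | None,
                         eps: float = 1e-5) -> np.ndarray:
        p = len(theta)
        H = np.empty((p, p))
        for j in range(p):
            tp, tm = theta.copy(), theta.copy()
            h = eps * max(1.0, abs(theta[j]))
            tp[j] += h
            tm[j] -= h
            gp = -self.group_scores(tp, fixed_tau).sum(axis=0)
            gm = -self.group_scores(tm, fixed_tau).sum(axis=0)
            H[j] = (gp - gm) / (2 * h)
        return 0.5 * (H + H.T)


def fit_first_hurdle(data: pd.DataFrame, spec: HurdleSpec) -> FitResult:
    """Fit the spray-decision probit with the spec's random intercept.

    The outcome is the spray indicator ``spray_<outcome>``.  Raises
    :class:`SeparationError` for degenerate outcomes and
    ``numpy.linalg.LinAlgError`` (naming the columns) for singular designs.
    """
    df, X, names, codes, dropped = _prepare(data, spec)
    y = df[f"spray_{spec.outcome}"].to_numpy(dtype=float)
    model = ProbitRE(y, X, codes, n_nodes=spec.n_nodes)
    raw = model.fit(tau2=spec.tau2, tol=spec.tol)
    free_tau = spec.tau2 is None
    H = raw["hessian"]
    vcov_model = _safe_inv(H)
    Sg = model.group_scores(raw["theta"], raw["fixed_tau"],
                            per_obs=(spec.vcov == "hc"))
    vcov_cluster = cluster_sandwich(Sg, vcov_model)
    return FitResult(
        params=raw["gamma"], names=names,
        vcov_model=vcov_model[: len(names), : len(names)],
        vcov_cluster=vcov_cluster[: len(names), : len(names)],
        sigma2=None, tau2=raw["tau"] ** 2, loglik=raw["loglik"],
        n_obs=len(y), n_groups=model.n_groups, converged=raw["converged"],
        scores=Sg,
    )


# ---------------------------------------------------------------------------
# Hurdle 2: random-intercept linear model on log outcome (ML)
# ---------------------------------------------------------------------------

class LinearRE:
    """ML random-intercept linear model, profiled over the variance ratio.

    With lambda = tau^2/sigma^2 fixed, the GLS estimate and the ML residual
    variance are closed-form (Woodbury on the intra-group equicorrelation), so
    only a 1-D search over lambda is needed.  ``lambda = 0`` reduces exactly
    to OLS with ML variance.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        order, starts = _sorted_groups(np.asarray(codes))
        self.order, self.starts = order, starts
        self.n_groups = len(starts)
        self.ys = self.y[order]
        self.Xs = self.X[order]
        self.ng = np.diff(np.r_[starts, len(self.y)])

    def _profile(self, lam: float):
        n, p = self.Xs.shape
        c = lam / (1.0 + self.ng * lam)  # per-group shrink factor
        sX = np.add.reduceat(self.Xs, self.starts, axis=0)
        sy = np.add.reduceat(self.ys, self.starts)
        XtX = self.Xs.T @ self.Xs - (sX * c[:, None]).T @ sX
        Xty = self.Xs.T @ self.ys - (sX * c[:, None]).T @ sy
        beta = np.linalg.solve(XtX, Xty)
        r = self.ys - self.Xs @ beta
        sr = np.add.reduceat(r, self.starts)
        rss = r @ r - (c * sr) @ sr
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + np.log1p(self.ng * lam).sum() + n)
        return beta, sigma2, ll, XtX

    def fit(self, tau2: float | None = None) -> dict:
        if len(self.y) <= self.X.shape[1]:
            raise ValueError("insufficient observations for the second hurdle")
        if tau2 is not None:
            if tau2 < 0:
                raise ConfigurationError("tau2 must be >= 0")
            # lam depends on sigma2; solve by fixed point (fast since sigma2
            # is nearly invariant); tau2=0 is exact in one step
            lam = 0.0 if tau2 == 0 else 1.0
            for _ in range(100):
                beta, sigma2, ll, XtX = self._profile(lam)
                new = 0.0 if tau2 == 0 else tau2 / sigma2
                if abs(new - lam) < 1e-12:
                    lam = new
                    break
                lam = new
            beta, sigma2, ll, XtX = self._profile(lam)
        else:
            def nll(loglam):
                return -self._profile(np.exp(loglam))[2]

            res = optimize.minimize_scalar(nll, bounds=(-20.0, 10.0), method="bounded",
                                           options={"xatol": 1e-12})
            lam = float(np.exp(res.x))
            _, _, ll0, _ = self._profile(lam)
            # honor the boundary when it beats the interior optimum
            _, _, ll_zero, _ = self._profile(0.0)
            if ll_zero >= ll0:
                lam = 0.0
            beta, sigma2, ll, XtX = self._profile(lam)
        tau2_hat = lam * sigma2
        vcov_beta = _safe_inv(XtX) * sigma2
        return {"beta": beta, "sigma2": float(sigma2), "tau2": float(tau2_hat),
                "lambda": lam, "loglik": float(ll), "vcov_beta": vcov_beta}

    def group_loglik(self, beta: np.ndarray, sigma2: float, tau2: float) -> np.ndarray:
        lam = tau2 / sigma2
        c = lam / (1.0 + self.ng * lam)
        r = self.ys - self.Xs @ beta
        sr = np.add.reduceat(r, self.starts)
        rss_g = np.add.reduceat(r * r, self.starts) - c * sr ** 2
        return -0.5 * (self.ng * np.log(2 * np.pi * sigma2)
                       + np.log1p(self.ng * lam) + rss_g / sigma2)

    def group_scores(self, beta: np.ndarray, sigma2: float, tau2: float,
                     free: tuple[bool, bool] = (True, True),
                     per_obs: bool = False) -> np.ndarray:
        """Scores w.r.t. (beta, [sigma2], [tau2]) per group, or per
        observation (``per_obs``, summing to the group scores; exact classic
        OLS scores when tau2 = 0).

        Beta scores are analytic; variance-parameter scores use central
        differences of the closed-form group log-likelihood (split evenly
        within a group in per-observation mode — only the beta block of the
        reported covariance depends on the split).
        """
        lam = tau2 / sigma2
        c = lam / (1.0 + self.ng * lam)
        r = self.ys - self.Xs @ beta
        sr = np.add.reduceat(r, self.starts)
        obs_group = np.repeat(np.arange(self.n_groups), self.ng)
        var_blocks = []
        if free[0]:
            h = 1e-6 * max(sigma2, 1e-8)
            d = (self.group_loglik(beta, sigma2 + h, tau2)
                 - self.group_loglik(beta, sigma2 - h, tau2)) / (2 * h)
            var_blocks.append(d)
        if free[1]:
            h = 1e-6 * max(tau2, 1e-8)
            lo = max(tau2 - h, 0.0)
            d = (self.group_loglik(beta, sigma2, tau2 + h)
                 - self.group_loglik(beta, sigma2, lo)) / (tau2 + h - lo)
            var_blocks.append(d)
        if per_obs:
            Sb = (self.Xs * (r - (c * sr)[obs_group])[:, None]) / sigma2
            blocks = [Sb] + [(d / self.ng)[obs_group, None] for d in var_blocks]
            return np.hstack(blocks)
        sX = np.add.reduceat(self.Xs, self.starts, axis=0)
        Sb = (np.add.reduceat(self.Xs * r[:, None], self.starts, axis=0)
              - (c * sr)[:, None] * sX) / sigma2
        return np.hstack([Sb] + [d[:, None] for d in var_blocks])


def fit_second_hurdle(data: pd.DataFrame, spec: HurdleSpec) -> FitResult:
    """Fit the log-amount linear mixed model on strictly positive outcomes.

    The caller passes the full table; rows with zero use are excluded here
    and any nonpositive outcome slipping through a caller-supplied subset
    raises.  ``spec.tau2 = 0`` reduces to OLS on logs (ML variance).
    """
    rate_col = f"rate_{spec.outcome}"
    if (data[rate_col] <= 0).any():
        raise ValueError(
            "second hurdle requires strictly positive outcomes; "
            "filter to spray > 0 before calling")
    df, X, names, codes, dropped = _prepare(data, spec)
    if len(df) < X.shape[1] + 1:
        raise ValueError("insufficient positive observations for the second hurdle")
    y = np.log(df[rate_col].to_numpy(dtype=float))
    model = LinearRE(y, X, codes)
    raw = model.fit(tau2=spec.tau2)
    free_tau = spec.tau2 is None and raw["tau2"] > 0
    Sg = model.group_scores(raw["beta"], raw["sigma2"], raw["tau2"],
                            free=(True, free_tau),
                            per_obs=(spec.vcov == "hc"))
    p = len(names)
    bread = np.zeros((Sg.shape[1], Sg.shape[1]))
    bread[:p, :p] = raw["vcov_beta"]
    # variance-parameter block of the bread from the numeric information
    Hvv = _variance_information(model, raw, free_tau)
    bread[p:, p:] = _safe_inv(Hvv)
    vcov_cluster = cluster_sandwich(Sg, bread)
    return FitResult(
        params=raw["beta"], names=names,
        vcov_model=raw["vcov_beta"],
        vcov_cluster=vcov_cluster[:p, :p],
        sigma2=raw["sigma2"], tau2=raw["tau2"], loglik=raw["loglik"],
        n_obs=len(y), n_groups=model.n_groups, converged=True, scores=Sg,
    )


def _variance_information(model: LinearRE, raw: dict, free_tau: bool) -> np.ndarray:
    params = [raw["sigma2"]] + ([raw["tau2"]] if free_tau else [])
    k = len(params)
    H = np.empty((k, k))

    def total(vals):
        s2 = vals[0]
        t2 = vals[1] if free_tau else raw["tau2"]
        return model.group_loglik(raw["beta"], s2, max(t2, 0.0)).sum()

    for i in range(k):
        for j in range(k):
            hi = 1e-4 * max(params[i], 1e-6)
            hj = 1e-4 * max(params[j], 1e-6)
            vpp = list(params); vpp[i] += hi; vpp[j] += hj
            vpm = list(params); vpm[i] += hi; vpm[j] -= hj
            vmp = list(params); vmp[i] -= hi; vmp[j] += hj
            vmm = list(params); vmm[i] -= hi; vmm[j] -= hj
            H[i, j] = -(total(vpp) - total(vpm) - total(vmp) + total(vmm)) / (4 * hi * hj)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# Sandwich, effects, transforms
# ---------------------------------------------------------------------------

def cluster_sandwich(group_scores: np.ndarray, bread: np.ndarray) -> np.ndarray:
    """Cluster-robust sandwich ``bread @ meat @ bread``.

    ``group_scores`` holds per-cluster summed score contributions (G x p);
    ``meat = sum_g s_g s_g'`` with small-sample factor ``G/(G-1)``.  With
    every observation its own cluster this is the HC formula with matching
    correction.  ``bread`` is the inverse (negative) Hessian.
    """
    S = np.atleast_2d(np.asarray(group_scores, dtype=float))
    G = S.shape[0]
    if G < 2:
        raise ValueError("cluster-robust variance requires at least 2 clusters")
    meat = S.T @ S * (G / (G - 1.0))
    return bread @ meat @ bread


def ame_organic(fit: FitResult, data: pd.DataFrame, spec: HurdleSpec | None = None,
                population_averaged: bool = False) -> EffectEstimate:
    """Discrete-change average marginal effect of the organic indicator.

    ``mean_i[Phi(x_i'gamma | organic=1) - Phi(x_i'gamma | organic=0)]`` with
    the random intercept set to zero (default) or integrated out
    (``population_averaged``, which rescales the index by
    ``1/sqrt(1 + tau^2)``).  The delta-method SE uses the fit's
    cluster-robust coefficient covariance.
    """
    if "organic" not in fit.names:
        raise ValueError("organic indicator is not in the fitted design")
    spec = spec or HurdleSpec()
    df, X, names, codes, _ = _prepare(data, spec)
    j = names.index("organic")
    X1, X0 = X.copy(), X.copy()
    X1[:, j] = 1.0
    X0[:, j] = 0.0
    gamma = fit.params
    scale = 1.0 / np.sqrt(1.0 + fit.tau2) if population_averaged else 1.0
    e1, e0 = scale * (X1 @ gamma), scale * (X0 @ gamma)
    ame = float(np.mean(norm.cdf(e1) - norm.cdf(e0)))
    grad = scale * (norm.pdf(e1)[:, None] * X1 - norm.pdf(e0)[:, None] * X0).mean(axis=0)
    se = float(np.sqrt(grad @ fit.vcov_cluster @ grad))
    return EffectEstimate("AME", "organic", ame, se)


def semi_elasticity(beta_j: float, se_j: float, target: str = "organic") -> EffectEstimate:
    """Percent change implied by a log-level coefficient: ``100(e^b - 1)``,
    with delta-method SE ``100 e^b se``."""
    est = 100.0 * (np.exp(beta_j) - 1.0)
    se = 100.0 * np.exp(beta_j) * se_j
    return EffectEstimate("semi-elasticity", target, float(est), float(se))


def ihs(x, premultiplier: float = 100.0):
    """Inverse hyperbolic sine of ``premultiplier * x``: log-like but defined
    at zero.  Interpretable like a log for large arguments."""
    z = premultiplier * np.asarray(x, dtype=float)
    return np.arcsinh(z)


# ---------------------------------------------------------------------------
# High-level fitting
# ---------------------------------------------------------------------------

def fit_double_hurdle(data: pd.DataFrame, spec: HurdleSpec) -> HurdleFit:
    """Fit both hurdles for one outcome and derive the reported effects."""
    h1 = fit_first_hurdle(data, spec)
    h2 = fit_second_hurdle(data[data[f"rate_{spec.outcome}"] > 0], spec)
    ame = ame_organic(h1, data, spec)
    b, se = h2.coef("organic")
    semi = semi_elasticity(b, se)
    return HurdleFit(h1=h1, h2=h2, ame=ame, semi=semi, outcome=spec.outcome)


def fit_crop_specific(data: pd.DataFrame, crop: str, spec: HurdleSpec) -> HurdleFit:
    """Refit both hurdles within one crop (year intercepts, HC-robust SEs).

    Requires the crop to appear under both management classes.  With fewer
    than two distinct years the random intercept degenerates and the model
    falls back to none (with a warning).
    """
    sub = data[data.crop == crop]
    if sub.organic.nunique() < 2:
        raise ValueError(f"crop {crop!r} lacks both organic and conventional fields")
    spec = HurdleSpec(outcome=spec.outcome, covariates=spec.covariates,
                      grouping="year", vcov="hc", n_nodes=spec.n_nodes,
                      tau2=spec.tau2, drop_imputed_soil=spec.drop_imputed_soil)
    if sub.year.nunique() < 2:
        warnings.warn(f"crop {crop!r} has <2 years; dropping the year intercept")
        spec.tau2 = 0.0
    return fit_double_hurdle(sub, spec)


def apply_yield_gap(data: pd.DataFrame, gap_table: dict[str, float]) -> pd.DataFrame:
    """Convert organic rows' per-area rates to yield-comparable rates.

    Each organic row's rate columns are multiplied by its crop group's
    multiplier (``all_crops`` fallback for unmapped crops); conventional rows
    and spray indicators are untouched, so the first hurdle is unaffected.
    """
    if "all_crops" not in gap_table:
        raise ConfigurationError("gap_table must supply an 'all_crops' default")
    for k, m in gap_table.items():
        if m <= 0:
            raise ConfigurationError(f"multiplier for {k!r} must be positive")
    df = data.copy()
    group = df.get("crop_group")
    if group is None:
        factors = pd.Series(gap_table["all_crops"], index=df.index)
    else:
        factors = group.map(gap_table).fillna(gap_table["all_crops"])
    factors = np.where(df.organic.to_numpy(dtype=bool), factors, 1.0)
    for col in df.columns:
        if col.startswith("rate_") or col == "pti_fish":
            df[col] = df[col] * factors
    return df


# ---------------------------------------------------------------------------
# Ancillary panel estimators
# ---------------------------------------------------------------------------

def fit_panel_ancillary(data: pd.DataFrame, estimator: str, spec: HurdleSpec,
                        group_col: str = "crop", premultiplier: float = 100.0):
    """Pooled OLS / within / random-effects panel models on IHS outcomes.

    The outcome and the size covariates are IHS-transformed (use rates
    pre-multiplied by ``premultiplier``); the within estimator differences
    all variables from their group means, absorbing group-level confounders.
    Returns ``(FitResult, comparison row dict)``.
    """
    df = data[data.family.notna()] if "family" in data.columns else data.copy()
    y = ihs(df[f"rate_{spec.outcome}"].to_numpy(dtype=float), premultiplier)
    X = np.column_stack([
        np.ones(len(df)),
        df.organic.to_numpy(dtype=float),
        ihs(df.area_adj_ha.to_numpy(dtype=float), 1.0),
        ihs(df.farm_size_ha.to_numpy(dtype=float), 1.0),
        df.storie.to_numpy(dtype=float),
    ])
    names = ["const", "organic", "ihs_area", "ihs_farm", "storie"]
    codes, _ = pd.factorize(df[group_col].astype(str), sort=True)

    if estimator == "within":
        counts = np.bincount(codes)
        if counts.max() < 2:
            raise ValueError("within estimator needs non-singleton groups")
        ybar = np.bincount(codes, weights=y) / counts
        yd = y - ybar[codes]
        Xd = np.empty_like(X)
        for j in range(X.shape[1]):
            xbar = np.bincount(codes, weights=X[:, j]) / counts
            Xd[:, j] = X[:, j] - xbar[codes]
        Xd = Xd[:, 1:]  # demeaning absorbs the constant
        beta, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
        r = yd - Xd @ beta
        sigma2 = float(r @ r / len(yd))
        XtX_inv = _safe_inv(Xd.T @ Xd)
        vc = cluster_sandwich(_ols_group_scores(Xd, r, codes), XtX_inv)
        ll = _gauss_loglik(r, sigma2)
        fit = FitResult(beta, names[1:], XtX_inv * sigma2, vc, sigma2, 0.0, ll,
                        len(yd), int(codes.max() + 1), True)
    elif estimator == "pooled-ols":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sigma2 = float(r @ r / len(y))
        XtX_inv = _safe_inv(X.T @ X)
        vc = cluster_sandwich(_ols_group_scores(X, r, codes), XtX_inv)
        ll = _gauss_loglik(r, sigma2)
        fit = FitResult(beta, names, XtX_inv * sigma2, vc, sigma2, 0.0, ll,
                        len(y), int(codes.max() + 1), True)
    elif estimator == "random-effects":
        model = LinearRE(y, X, codes)
        raw = model.fit()
        Sg = model.group_scores(raw["beta"], raw["sigma2"], raw["tau2"],
                                free=(True, raw["tau2"] > 0))
        p = X.shape[1]
        bread = np.zeros((Sg.shape[1], Sg.shape[1]))
        bread[:p, :p] = raw["vcov_beta"]
        if Sg.shape[1] > p:
            bread[p:, p:] = _safe_inv(_variance_information(model, raw, raw["tau2"] > 0))
        vc = cluster_sandwich(Sg, bread)[:p, :p]
        fit = FitResult(raw["beta"], names, raw["vcov_beta"], vc, raw["sigma2"],
                        raw["tau2"], raw["loglik"], len(y), model.n_groups, True)
    else:
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    comparison = {"estimator": estimator, "loglik": fit.loglik, "aic": fit.aic,
                  "bic": fit.bic, "organic": fit.coef("organic")[0]}
    return fit, comparison


def _ols_group_scores(X: np.ndarray, r: np.ndarray, codes: np.ndarray) -> np.ndarray:
    # group sums of x_i r_i; paired with bread (X'X)^{-1} the sigma^2 factors
    # of the Gaussian score and Hessian cancel
    per_obs = X * r[:, None]
    order, starts = _sorted_groups(codes)
    return np.add.reduceat(per_obs[order], starts, axis=0)


def _gauss_loglik(r: np.ndarray, sigma2: float) -> float:
    n = len(r)
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + n))


def _safe_inv(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)
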