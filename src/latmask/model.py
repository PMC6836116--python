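"""Binomial probit mixed-effects model for 2AFC psychometric data.

The model for trial outcome :math:`y_{ij}` of observer :math:`i` is

.. math::

    P(y_{ij} = 1 \\mid b_i) = \\Phi(x_{ij}'\\beta + z_{ij}'b_i),
    \\qquad b_i \\sim N(0, \\Sigma),

with fixed effects :math:`\\beta` (intercept, contrast slope, group terms and
optional flanker-distance terms) and a bivariate random effect per observer:
an intercept and a contrast slope, with unstructured 2x2 covariance
:math:`\\Sigma`.

Estimation maximises the marginal likelihood

.. math::

    \\prod_i \\int \\prod_j \\Phi(\\eta_{ij})^{y_{ij}}
        (1-\\Phi(\\eta_{ij}))^{1-y_{ij}} \\; \\phi(b; 0, \\Sigma)\\, db

with the observer-level integrals evaluated by adaptive Gauss-Hermite
quadrature (tensor-product nodes centred and scaled at each observer's
conditional mode).  :math:`\\Sigma` is parameterised by its Cholesky factor,
so the estimate is positive semi-definite by construction.  ``n_quad=1``
gives the Laplace approximation.

The interface follows the model/results split of statsmodels:
``ProbitGLMM.from_trials(table, spec).fit()`` returns a
:class:`ProbitGLMMResults` carrying estimates, covariances, the Wald table
and prediction helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_ndtr, logsumexp, ndtr

from .design import BASELINE, condition_distance
from .simulate import CONTROL, GROUPS, MIGRAINE_AURA, ValidationError

__all__ = [
    "ModelSpec",
    "DesignBundle",
    "ProbitGLMM",
    "ProbitGLMMResults",
    "ConvergenceError",
    "baseline_spec",
    "flanker_spec",
    "build_design",
    "fit_probit_glmm",
    "predict_p",
]

#: Recognised fixed-effect term names, in canonical column order.
FIXED_TERMS = (
    "intercept",
    "contrast",
    "group",
    "group:contrast",
    "distance",
    "contrast:distance",
    "group:distance",
    "group:contrast:distance",
)

RANDOM_TERMS = ("intercept", "contrast")


class ConvergenceError(RuntimeError):
    """Raised when an operation requires a converged fit and none is available."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model specification (term names, random part, link)."""

    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...] = RANDOM_TERMS
    link: str = "probit"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(self, "random_terms", tuple(self.random_terms))
        unknown = [t for t in self.fixed_terms if t not in FIXED_TERMS]
        if unknown:
            raise ValidationError(f"unknown fixed terms {unknown}; allowed: {FIXED_TERMS}")
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValidationError("fixed term list contains duplicates")
        if not set(self.random_terms) <= set(RANDOM_TERMS):
            raise ValidationError(f"random terms must be a subset of {RANDOM_TERMS}")
        if self.link != "probit":
            raise ValidationError("only the probit link is supported")

    @property
    def uses_distance(self) -> bool:
        return any("distance" in t for t in self.fixed_terms)

    @property
    def uses_group(self) -> bool:
        return any("group" in t for t in self.fixed_terms)


def baseline_spec() -> ModelSpec:
    """Baseline (no-flanker) model: contrast, group, and their interaction."""
    return ModelSpec(("intercept", "contrast", "group", "group:contrast"))


def flanker_spec() -> ModelSpec:
    """Flanker model: adds distance and the three stated interactions."""
    return ModelSpec(
        (
            "intercept",
            "contrast",
            "group",
            "group:contrast",
            "distance",
            "contrast:distance",
            "group:distance",
            "group:contrast:distance",
        )
    )


@dataclass
class DesignBundle:
    """Matrices for one fit: fixed design, random design, grouping, response."""

    X: np.ndarray            # (N, p) fixed-effects design
    Z: np.ndarray            # (N, q) random-effects design
    group_idx: np.ndarray    # (N,) observer index in [0, n_obs)
    successes: np.ndarray    # (N,) correct counts
    trials: np.ndarray       # (N,) trial counts (all 1 for Bernoulli coding)
    observer_ids: list       # n_obs labels, index-aligned with group_idx
    spec: ModelSpec
    coding: str

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_obs(self) -> int:
        return len(self.observer_ids)


def _term_column(term: str, contrast, group, distance) -> np.ndarray:
    parts = term.split(":")
    col = np.ones_like(contrast)
    for part in parts:
        if part == "intercept":
            continue
        elif part == "contrast":
            col = col * contrast
        elif part == "group":
            col = col * group
        elif part == "distance":
            col = col * distance
    return col


def build_design(
    trials: pd.DataFrame, spec: ModelSpec, coding: str = "binomial"
) -> DesignBundle:
    """Build design matrices from a trial table.

    ``coding='bernoulli'`` keeps one row per trial; ``coding='binomial'``
    aggregates to one row per (observer, condition, contrast) cell with
    success/trial counts.  Both give identical likelihoods and estimates.
    The control group is the reference level (coded 0).
    """
    if coding not in ("bernoulli", "binomial"):
        raise ValidationError(f"unknown coding {coding!r}")
    missing = [c for c in ("observer_id", "group", "condition", "contrast", "correct") if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table lacks required columns {missing}")
    df = trials
    bad_groups = set(df["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown group labels {sorted(bad_groups)}")
    if spec.uses_group and df["group"].nunique() < 2:
        raise ValidationError("model includes group terms but the data hold a single group")

    # validates condition tokens as a side effect
    dist_map = {c: condition_distance(c) for c in df["condition"].unique()}
    if spec.uses_distance:
        keep = df["condition"] != BASELINE
        df = df[keep]
        if df.empty:
            raise ValidationError("distance terms requested but only baseline rows present")

    if coding == "binomial":
        cells = (
            df.groupby(["observer_id", "group", "condition", "contrast"], sort=True)["correct"]
            .agg(successes="sum", trials="count")
            .reset_index()
        )
        successes = cells["successes"].to_numpy(dtype=np.float64)
        n_trials = cells["trials"].to_numpy(dtype=np.float64)
        frame = cells
    else:
        frame = df.sort_values(["observer_id", "condition", "contrast"], kind="stable")
        successes = frame["correct"].to_numpy(dtype=np.float64)
        if not np.isin(successes, (0.0, 1.0)).all():
            raise ValidationError("correct must be 0/1 in bernoulli coding")
        n_trials = np.ones_like(successes)

    contrast = frame["contrast"].to_numpy(dtype=np.float64)
    group = (frame["group"] == MIGRAINE_AURA).to_numpy(dtype=np.float64)
    distance = np.array(
        [0.0 if dist_map[c] is None else dist_map[c] for c in frame["condition"]],
        dtype=np.float64,
    )

    X = np.column_stack(
        [_term_column(t, contrast, group, distance) for t in spec.fixed_terms]
    )
    z_cols = {"intercept": np.ones_like(contrast), "contrast": contrast}
    Z = np.column_stack([z_cols[t] for t in spec.random_terms])

    observer_ids = sorted(frame["observer_id"].unique())
    idx_of = {o: i for i, o in enumerate(observer_ids)}
    group_idx = frame["observer_id"].map(idx_of).to_numpy(dtype=np.int64)

    return DesignBundle(
        X=np.ascontiguousarray(X),
        Z=np.ascontiguousarray(Z),
        group_idx=group_idx,
        successes=successes,
        trials=n_trials,
        observer_ids=observer_ids,
        spec=spec,
        coding=coding,
    )


# ---------------------------------------------------------------------------
# likelihood machinery


def _bernoulli_loglik(eta, k, n):
    """sum k*log Phi(eta) + (n-k)*log Phi(-eta), elementwise terms."""
    return k * log_ndtr(eta) + (n - k) * log_ndtr(-eta)


def _eta_derivs(eta, k, n):
    """First and second derivatives of the Bernoulli probit loglik in eta."""
    # a = phi/Phi evaluated stably on both tails
    log_phi = -0.5 * eta**2 - 0.5 * np.log(2 * np.pi)
    a = np.exp(log_phi - log_ndtr(eta))
    c = np.exp(log_phi - log_ndtr(-eta))
    g = k * a - (n - k) * c
    h = -k * a * (eta + a) + (n - k) * (eta * c - c * c)
    return g, h


class _MarginalLoglik:
    """Vectorised marginal loglikelihood with cached conditional modes."""

    def __init__(self, bundle: DesignBundle, n_quad: int):
        self.b = bundle
        self.q = bundle.Z.shape[1]
        nodes, weights = np.polynomial.hermite.hermgauss(max(1, n_quad))
        if self.q == 1:
            self.t = nodes[:, None]
            self.logw = np.log(weights)
        else:
            t0, t1 = np.meshgrid(nodes, nodes, indexing="ij")
            self.t = np.column_stack([t0.ravel(), t1.ravel()])
            self.logw = np.add.outer(np.log(weights), np.log(weights)).ravel()
        self.modes = np.zeros((bundle.n_obs, self.q))

    # -- conditional pieces -------------------------------------------------

    def _cond_loglik_per_obs(self, beta, b):
        """log p(y_i | b_i) for per-observer random effects b (n_obs, q)."""
        d = self.b
        eta = d.X @ beta + np.einsum("nq,nq->n", d.Z, b[d.group_idx])
        ll = _bernoulli_loglik(eta, d.successes, d.trials)
        return np.bincount(d.group_idx, weights=ll, minlength=d.n_obs)

    def _find_modes(self, beta, prec, logdet_sigma):
        """Newton ascent of the joint log-density, all observers at once."""
        d = self.b
        b = self.modes.copy()
        xb = d.X @ beta
        for _ in range(100):
            eta = xb + np.einsum("nq,nq->n", d.Z, b[d.group_idx])
            g_eta, h_eta = _eta_derivs(eta, d.successes, d.trials)
            # gradient: sum_j g_eta z_j - prec @ b
            grad = np.column_stack(
                [
                    np.bincount(d.group_idx, weights=g_eta * d.Z[:, q], minlength=d.n_obs)
                    for q in range(self.q)
                ]
            ) - b @ prec
            # negative Hessian: prec - sum_j h_eta z_j z_j'
            H = np.empty((d.n_obs, self.q, self.q))
            for q1 in range(self.q):
                for q2 in range(q1, self.q):
                    acc = np.bincount(
                        d.group_idx,
                        weights=h_eta * d.Z[:, q1] * d.Z[:, q2],
                        minlength=d.n_obs,
                    )
                    H[:, q1, q2] = prec[q1, q2] - acc
                    H[:, q2, q1] = H[:, q1, q2]
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            b = b + step
            if np.abs(step).max() < 1e-11:
                break
        self.modes = b
        eta = xb + np.einsum("nq,nq->n", d.Z, b[d.group_idx])
        _, h_eta = _eta_derivs(eta, d.successes, d.trials)
        H = np.empty((d.n_obs, self.q, self.q))
        for q1 in range(self.q):
            for q2 in range(q1, self.q):
                acc = np.bincount(
                    d.group_idx, weights=h_eta * d.Z[:, q1] * d.Z[:, q2], minlength=d.n_obs
                )
                H[:, q1, q2] = prec[q1, q2] - acc
                H[:, q2, q1] = H[:, q1, q2]
        return b, H

    # -- public entry points ------------------------------------------------

    def loglik_fixed_only(self, beta):
        d = self.b
        eta = d.X @ beta
        return float(_bernoulli_loglik(eta, d.successes, d.trials).sum())

    def loglik(self, beta, L):
        """Marginal loglik by adaptive GH quadrature; L = chol factor of Sigma."""
        d = self.b
        sigma = L @ L.T
        try:
            chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(self.q))
        except np.linalg.LinAlgError:
            return -np.inf
        prec = np.linalg.inv(sigma + 1e-12 * np.eye(self.q))
        logdet_sigma = 2.0 * np.log(np.diag(chol)).sum()

        modes, H = self._find_modes(beta, prec, logdet_sigma)
        # scale matrices C_i with H_i^{-1} = C_i C_i'
        Hinv = np.linalg.inv(H)
        C = np.linalg.cholesky(Hinv)
        # quadrature points b_ik = mode_i + sqrt(2) C_i t_k
        shift = np.sqrt(2.0) * np.einsum("iqr,kr->ikq", C, self.t)
        b_nodes = modes[:, None, :] + shift  # (n_obs, K, q)

        xb = d.X @ beta
        eta = xb[:, None] + np.einsum(
            "nq,nkq->nk", d.Z, b_nodes[d.group_idx]
        )  # (N, K)
        ll_rows = _bernoulli_loglik(eta, d.successes[:, None], d.trials[:, None])
        cond = np.zeros((d.n_obs, eta.shape[1]))
        np.add.at(cond, d.group_idx, ll_rows)

        # prior density at the nodes
        quad_form = np.einsum("ikq,qr,ikr->ik", b_nodes, prec, b_nodes)
        log_prior = -0.5 * (quad_form + logdet_sigma + self.q * np.log(2 * np.pi))

        tsq = (self.t**2).sum(axis=1)
        _, logdetC = np.linalg.slogdet(C)
        per_obs = (
            0.5 * self.q * np.log(2.0)
            + logdetC
            + logsumexp(self.logw[None, :] + tsq[None, :] + cond + log_prior, axis=1)
        )
        return float(per_obs.sum())


def _pack_L(L: np.ndarray) -> np.ndarray:
    q = L.shape[0]
    return L[np.tril_indices(q)]


def _unpack_L(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = theta
    return L


def _fit_fixed_only(ml: _MarginalLoglik, beta0: np.ndarray):
    """Newton maximisation of the no-random-effect probit loglikelihood."""
    d = ml.b
    beta = beta0.copy()
    for _ in range(100):
        eta = d.X @ beta
        g_eta, h_eta = _eta_derivs(eta, d.successes, d.trials)
        grad = d.X.T @ g_eta
        hess = (d.X * h_eta[:, None]).T @ d.X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta - step
        if np.abs(step).max() < 1e-10:
            break
    return beta


def _numerical_hessian(f, x0, rel_step=1e-4):
    """Central-difference Hessian of scalar f at x0."""
    n = x0.size
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x0.copy(), x0.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f(x0) + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4.0 * h[i] * h[j]
                )
    return H


class ProbitGLMM:
    """Probit-link binomial mixed model with per-observer random effects.

    Construct from matrices (a :class:`DesignBundle`) or, more typically,
    from a trial table via :meth:`from_trials`.
    """

    def __init__(self, bundle: DesignBundle):
        if bundle.n_obs < 2:
            raise ValidationError("a mixed model needs at least 2 observers")
        self.bundle = bundle
        self._warn_separation()

    @classmethod
    def from_trials(
        cls,
        trials: pd.DataFrame,
        spec: ModelSpec | None = None,
        coding: str = "binomial",
    ) -> "ProbitGLMM":
        spec = spec if spec is not None else baseline_spec()
        return cls(build_design(trials, spec, coding=coding))

    def _warn_separation(self) -> None:
        d = self.bundle
        all_correct = np.bincount(
            d.group_idx, weights=d.trials - d.successes, minlength=d.n_obs
        )
        perfect = [d.observer_ids[i] for i in np.flatnonzero(all_correct == 0)]
        if perfect:
            warnings.warn(
                f"observers with all-correct responses (quasi-separation): {perfect}",
                UserWarning,
                stacklevel=3,
            )

    # -- fitting ------------------------------------------------------------

    def loglike(self, beta, sigma_re=None, n_quad: int = 7) -> float:
        """Marginal loglikelihood at given parameters (Sigma=None or 0 -> GLM)."""
        ml = _MarginalLoglik(self.bundle, n_quad)
        beta = np.asarray(beta, dtype=float)
        if sigma_re is None or not np.any(np.asarray(sigma_re)):
            return ml.loglik_fixed_only(beta)
        L = np.linalg.cholesky(np.asarray(sigma_re, dtype=float))
        return ml.loglik(beta, L)

    def fit(
        self,
        n_quad: int = 7,
        fix_sigma: np.ndarray | None = None,
        start_beta: np.ndarray | None = None,
        start_sigma: np.ndarray | None = None,
        compute_cov: bool = True,
        gtol: float = 1e-5,
        ftol_rel: float = 1e-11,
        maxiter: int = 500,
    ) -> "ProbitGLMMResults":
        """Maximise the marginal likelihood.

        Parameters
        ----------
        n_quad
            Gauss-Hermite nodes per random-effect dimension; 1 = Laplace.
        fix_sigma
            Pin the random-effects covariance at this matrix instead of
            estimating it.  The zero matrix collapses the model to a plain
            probit GLM (the quadrature is exact there).
        compute_cov
            Whether to compute the observed-information covariance of the
            estimates (skippable for speed inside bootstrap loops).
        """
        d = self.bundle
        q = d.Z.shape[1]
        p = d.X.shape[1]
        ml = _MarginalLoglik(d, n_quad)

        beta_glm = _fit_fixed_only(
            ml, np.asarray(start_beta, dtype=float) if start_beta is not None else np.zeros(p)
        )
        glm_loglik = ml.loglik_fixed_only(beta_glm)
        beta0 = np.asarray(start_beta, dtype=float) if start_beta is not None else beta_glm

        if fix_sigma is not None and not np.any(np.asarray(fix_sigma)):
            # Sigma pinned at zero: plain probit GLM by Newton.
            beta_hat = _fit_fixed_only(ml, beta0)
            loglik = ml.loglik_fixed_only(beta_hat)
            eta = d.X @ beta_hat
            _, h_eta = _eta_derivs(eta, d.successes, d.trials)
            info = -(d.X * h_eta[:, None]).T @ d.X
            cov_beta = np.linalg.inv(info) if compute_cov else None
            return ProbitGLMMResults(
                model=self,
                beta=beta_hat,
                cov_beta=cov_beta,
                sigma_re=np.zeros((q, q)),
                sigma_fixed=True,
                loglik=float(loglik),
                converged=True,
                n_iter=0,
                n_quad=n_quad,
            )

        if fix_sigma is not None:
            L_fixed = np.linalg.cholesky(
                np.asarray(fix_sigma, dtype=float) + 1e-12 * np.eye(q)
            )

            def negll(params):
                return -ml.loglik(params, L_fixed)

            x0 = beta0
        else:
            sigma0 = (
                np.asarray(start_sigma, dtype=float)
                if start_sigma is not None
                else 0.1 * np.eye(q)
            )
            L0 = np.linalg.cholesky(sigma0 + 1e-10 * np.eye(q))

            def negll(params):
                return -ml.loglik(params[:p], _unpack_L(params[p:], q))

            x0 = np.concatenate([beta0, _pack_L(L0)])

        # L-BFGS-B with finite-difference gradients can stop with an abnormal
        # line-search near the optimum; restart there and accept stationarity
        # when successive restarts no longer improve the loglikelihood.
        res = None
        with np.errstate(over="ignore", invalid="ignore"):
            x_start = x0
            for attempt in range(3):
                prev_fun = res.fun if res is not None else np.inf
                res = optimize.minimize(
                    negll,
                    x_start,
                    method="L-BFGS-B",
                    options={
                        "maxiter": maxiter,
                        "ftol": ftol_rel,
                        "gtol": gtol,
                        "maxcor": 25,
                    },
                )
                if res.success:
                    break
                if prev_fun - res.fun < 1e-6 * (1.0 + abs(res.fun)):
                    res.success = True  # stationary across restarts
                    break
                x_start = res.x
        beta_hat = res.x[:p]
        if fix_sigma is not None:
            sigma_hat = np.asarray(fix_sigma, dtype=float)
        else:
            L_hat = _unpack_L(res.x[p:], q)
            sigma_hat = L_hat @ L_hat.T
        loglik = -res.fun
        if fix_sigma is None and loglik < glm_loglik:
            # the marginal likelihood is maximised on the Sigma=0 boundary,
            # where the plain probit optimum is exact; return it directly
            eta = d.X @ beta_glm
            _, h_eta = _eta_derivs(eta, d.successes, d.trials)
            info = -(d.X * h_eta[:, None]).T @ d.X
            return ProbitGLMMResults(
                model=self,
                beta=beta_glm,
                cov_beta=np.linalg.inv(info) if compute_cov else None,
                sigma_re=np.zeros((q, q)),
                sigma_fixed=False,
                loglik=float(glm_loglik),
                converged=True,
                n_iter=int(res.nit),
                n_quad=n_quad,
            )
        converged = bool(res.success and np.isfinite(loglik))
        if not converged:
            warnings.warn(
                f"mixed-model optimiser did not converge: {res.message}",
                UserWarning,
                stacklevel=2,
            )

        cov_beta = None
        if compute_cov:
            H = _numerical_hessian(negll, res.x)
            try:
                cov_all = np.linalg.inv(H)
                cov_beta = cov_all[:p, :p]
                # guard against a non-PD numerical Hessian
                if not np.all(np.isfinite(cov_beta)) or np.any(
                    np.diag(cov_beta) <= 0
                ):
                    cov_beta = np.linalg.inv(H[:p, :p])
            except np.linalg.LinAlgError:
                cov_beta = np.linalg.pinv(H)[:p, :p]
                converged = converged and np.all(np.diag(cov_beta) > 0)
            cov_beta = 0.5 * (cov_beta + cov_beta.T)

        return ProbitGLMMResults(
            model=self,
            beta=beta_hat,
            cov_beta=cov_beta,
            sigma_re=sigma_hat,
            sigma_fixed=fix_sigma is not None,
            loglik=float(loglik),
            converged=converged,
            n_iter=int(res.nit),
            n_quad=n_quad,
        )


@dataclass
class ProbitGLMMResults:
    """Fitted probit GLMM: estimates, covariances, diagnostics."""

    model: ProbitGLMM
    beta: np.ndarray
    cov_beta: np.ndarray | None
    sigma_re: np.ndarray
    sigma_fixed: bool
    loglik: float
    converged: bool
    n_iter: int
    n_quad: int

    @property
    def term_names(self) -> tuple[str, ...]:
        return self.model.bundle.spec.fixed_terms

    @property
    def n_rows(self) -> int:
        return self.model.bundle.n_rows

    @property
    def df_resid(self) -> int:
        """Residual degrees of freedom: design rows minus fixed-effect count."""
        return self.n_rows - self.beta.size

    def bse(self) -> np.ndarray:
        if self.cov_beta is None:
            raise ValueError("fit was run with compute_cov=False")
        return np.sqrt(np.diag(self.cov_beta))

    def wald_table(self) -> pd.DataFrame:
        """Per-term estimate, SE, t, residual dof and two-sided p."""
        if not self.converged:
            raise ConvergenceError("Wald report requires a converged fit")
        se = self.bse()
        if np.any(se == 0):
            raise ValueError("zero standard error; Wald statistics undefined")
        t = self.beta / se
        dof = self.df_resid
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": se,
                "t": t,
                "dof": dof,
                "p": p,
            },
            index=list(self.term_names),
        )

    # -- prediction ---------------------------------------------------------

    def linear_predictor(
        self, contrast, group: str = CONTROL, distance: float = 0.0, observer_effects=None
    ) -> np.ndarray:
        contrast = np.asarray(contrast, dtype=float)
        g = 1.0 if group == MIGRAINE_AURA else 0.0
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        eta = np.zeros_like(contrast)
        for term, b in zip(self.term_names, self.beta):
            eta = eta + b * _term_column(
                term, contrast, np.full_like(contrast, g), np.full_like(contrast, distance)
            )
        if observer_effects is not None:
            b0, b1 = observer_effects
            eta = eta + b0 + b1 * contrast
        return eta

    def predict_p(
        self, contrast, group: str = CONTROL, distance: float = 0.0, observer_effects=None
    ) -> np.ndarray:
        """Predicted proportion correct Phi(x'beta [+ z'b])."""
        return ndtr(self.linear_predictor(contrast, group, distance, observer_effects))

    def group_psychometric(self, group: str, distance: float = 0.0) -> tuple[float, float]:
        """Population-average (intercept, slope) in contrast for one group."""
        eta0 = float(self.linear_predictor(0.0, group, distance))
        eta1 = float(self.linear_predictor(1.0, group, distance))
        return eta0, eta1 - eta0

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Probit mixed-effects model (binomial responses)",
            f"  rows: {self.n_rows} ({self.model.bundle.coding} coding)"
            f"   observers: {self.model.bundle.n_obs}",
            f"  loglik: {self.loglik:.4f}   converged: {self.converged}"
            f"   quadrature: {self.n_quad}^{self.model.bundle.Z.shape[1]} nodes",
            "",
        ]
        if self.cov_beta is not None and self.converged:
            table = self.wald_table()
            lines.append(table.to_string(float_format=lambda v: f"{v:10.4f}"))
        else:
            for name, b in zip(self.term_names, self.beta):
                lines.append(f"  {name:>26s} {b:12.4f}")
        lines.append("")
        label = "fixed" if self.sigma_fixed else "estimated"
        lines.append(f"Random-effects covariance ({label}; observer intercept, contrast slope):")
        for row in self.sigma_re:
            lines.append("  " + "  ".join(f"{v:12.5f}" for v in row))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "terms": list(self.term_names),
            "beta": [float(b) for b in self.beta],
            "sigma_re": [[float(v) for v in row] for row in self.sigma_re],
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_quad": self.n_quad,
            "n_rows": self.n_rows,
            "n_observers": self.model.bundle.n_obs,
            "coding": self.model.bundle.coding,
        }
        if self.cov_beta is not None:
            out["cov_beta"] = [[float(v) for v in row] for row in self.cov_beta]
            if self.converged:
                out["wald"] = {
                    name: {
                        "estimate": float(r.estimate),
                        "se": float(r.se),
                        "t": float(r.t),
                        "dof": int(r.dof),
                        "p": float(r.p),
                    }
                    for name, r in self.wald_table().iterrows()
                }
        return out


def fit_probit_glmm(
    trials: pd.DataFrame, spec: ModelSpec | None = None, **fit_kwargs
) -> ProbitGLMMResults:
    """One-call convenience: build the design and fit."""
    return ProbitGLMM.from_trials(trials, spec).fit(**fit_kwargs)


def predict_p(fit: ProbitGLMMResults, contrast, **kwargs) -> np.ndarray:
    """Functional alias for :meth:`ProbitGLMMResults.predict_p`."""
    return fit.predict_p(contrast, **kwargs)
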