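"""75%-correct contrast thresholds and their parametric-bootstrap uncertainty.

A psychometric function with probit intercept :math:`a` and contrast slope
:math:`m` crosses criterion probability :math:`c` at

.. math::  T = (\\Phi^{-1}(c) - a) / m .

Uncertainty is quantified by the parametric bootstrap used in the study:
each bootstrap sample draws a fresh population of simulated observers from
the fitted group-level estimates and covariance, simulates binomial 2AFC
responses across the session's contrast levels through the probit link,
refits the same mixed model, and recomputes each group's threshold.  The
standard deviation of the resampled thresholds is the reported error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .design import SessionDesign
from .model import ProbitGLMM, ProbitGLMMResults, ConvergenceError, DesignBundle
from .simulate import CONTROL, GROUPS, MIGRAINE_AURA, ValidationError

__all__ = [
    "ThresholdEstimate",
    "BootstrapSummary",
    "threshold_75",
    "group_thresholds",
    "bootstrap_threshold_sd",
    "compare_group_thresholds",
]


@dataclass(frozen=True)
class ThresholdEstimate:
    """Contrast at criterion performance for one group x condition cell."""

    group: str
    condition: str
    threshold: float
    criterion: float = 0.75
    sd: float | None = None


def threshold_75(intercept: float, slope: float, criterion: float = 0.75) -> float:
    """Contrast at which Phi(intercept + slope*c) equals the criterion.

    Raises for a zero slope; a negative slope yields a (degenerate) threshold
    with a warning, since the function then decreases through the criterion.
    """
    if not (0.0 < criterion < 1.0):
        raise ValidationError(f"criterion must lie in (0,1), got {criterion}")
    if slope == 0:
        raise ValidationError("threshold undefined: zero contrast slope")
    if slope < 0:
        warnings.warn(
            "negative contrast slope: threshold is degenerate", UserWarning, stacklevel=2
        )
    return (ndtri(criterion) - intercept) / slope


def group_thresholds(
    fit: ProbitGLMMResults, criterion: float = 0.75, distance: float = 0.0
) -> dict[str, float]:
    """Population-average threshold per group from a fitted model."""
    out = {}
    groups = [CONTROL, MIGRAINE_AURA] if fit.model.bundle.spec.uses_group else [CONTROL]
    for group in groups:
        a, m = fit.group_psychometric(group, distance=distance)
        out[group] = threshold_75(a, m, criterion)
    return out


@dataclass
class BootstrapSummary:
    """Parametric-bootstrap threshold draws and derived uncertainty."""

    n_samples: int
    thresholds: dict[str, np.ndarray]   # per-group draws, aligned across groups
    sd: dict[str, float]
    point: dict[str, float]             # thresholds from the original fit
    n_dropped: int
    criterion: float
    seed: int
    covariance_mode: str

    def difference_draws(self) -> np.ndarray:
        """Migraine minus control threshold, per bootstrap sample."""
        if set(self.thresholds) != set(GROUPS):
            raise ValidationError("difference requires both groups in the summary")
        return self.thresholds[MIGRAINE_AURA] - self.thresholds[CONTROL]

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_dropped": self.n_dropped,
            "criterion": self.criterion,
            "seed": self.seed,
            "covariance_mode": self.covariance_mode,
            "point": {g: float(v) for g, v in self.point.items()},
            "sd": {g: float(v) for g, v in self.sd.items()},
        }


def _group_sampling_cov(fit: ProbitGLMMResults, group: str) -> np.ndarray:
    """Sampling covariance of a group's (intercept, slope) from cov_beta."""
    if fit.cov_beta is None:
        raise ValidationError("fit lacks cov_beta; rerun fit with compute_cov=True")
    terms = list(fit.term_names)
    p = len(terms)
    grad_a = np.zeros(p)
    grad_m = np.zeros(p)
    grad_a[terms.index("intercept")] = 1.0
    grad_m[terms.index("contrast")] = 1.0
    if group == MIGRAINE_AURA:
        grad_a[terms.index("group")] = 1.0
        grad_m[terms.index("group:contrast")] = 1.0
    J = np.vstack([grad_a, grad_m])
    return J @ fit.cov_beta @ J.T


def _simulate_refit_bundle(
    observers: np.ndarray,
    group_codes: np.ndarray,
    design: SessionDesign,
    rng: np.random.Generator,
    template: DesignBundle,
) -> DesignBundle:
    """Binomial-coded bundle for one bootstrap sample, built without pandas."""
    levels = np.asarray(design.contrast_levels)
    n_obs = observers.shape[0]
    reps = design.reps_per_level
    eta = observers[:, 0][:, None] + observers[:, 1][:, None] * levels[None, :]
    k = rng.binomial(reps, ndtr(eta))
    N = n_obs * levels.size
    contrast = np.tile(levels, n_obs)
    group = np.repeat(group_codes, levels.size).astype(np.float64)
    ones = np.ones(N)
    cols = {
        "intercept": ones,
        "contrast": contrast,
        "group": group,
        "group:contrast": group * contrast,
    }
    X = np.column_stack([cols[t] for t in template.spec.fixed_terms])
    z_map = {"intercept": ones, "contrast": contrast}
    Z = np.column_stack([z_map[t] for t in template.spec.random_terms])
    return DesignBundle(
        X=X,
        Z=Z,
        group_idx=np.repeat(np.arange(n_obs), levels.size),
        successes=k.ravel().astype(np.float64),
        trials=np.full(N, float(reps)),
        observer_ids=list(range(n_obs)),
        spec=template.spec,
        coding="binomial",
    )


def bootstrap_threshold_sd(
    fit: ProbitGLMMResults,
    group_sizes: tuple[int, int],
    design: SessionDesign,
    n_samples: int = 1000,
    seed: int = 0,
    criterion: float = 0.75,
    covariance_mode: str = "random_effects",
    refit_sigma: str = "estimate",
    n_quad: int | None = None,
    max_dropped_frac: float = 0.2,
) -> BootstrapSummary:
    """Parametric bootstrap of the group 75% thresholds.

    Each sample (1) draws per-observer (intercept, slope) pairs around each
    group's fitted fixed effects, (2) simulates binomial responses over the
    design's contrast levels through the probit link, (3) refits the same
    mixed model, and (4) recomputes each group's threshold.

    Parameters
    ----------
    covariance_mode
        ``'random_effects'`` (default) spreads simulated observers with the
        fitted random-effects covariance — a population of heterogeneous
        observers.  ``'fixed_effects'`` spreads them with the sampling
        covariance of the group's fixed-effect (intercept, slope) instead.
    refit_sigma
        ``'estimate'`` re-estimates the random-effects covariance on every
        bootstrap refit; ``'zero'`` pins it at zero (a plain probit refit,
        appropriate — and fast — when the fitted covariance is zero).
    n_quad
        Quadrature order for refits; defaults to the original fit's order.
    """
    if not fit.converged:
        raise ConvergenceError("bootstrap requires a converged fit")
    if covariance_mode not in ("random_effects", "fixed_effects"):
        raise ValidationError(f"unknown covariance_mode {covariance_mode!r}")
    if refit_sigma not in ("estimate", "zero"):
        raise ValidationError(f"unknown refit_sigma {refit_sigma!r}")
    if any(n < 1 for n in group_sizes):
        raise ValidationError("group sizes must be positive")
    if not fit.model.bundle.spec.uses_group:
        raise ValidationError("bootstrap group comparison needs a model with group terms")
    n_quad = n_quad if n_quad is not None else fit.n_quad

    rng = np.random.default_rng(seed)
    means = {g: np.array(fit.group_psychometric(g)) for g in GROUPS}
    if covariance_mode == "random_effects":
        covs = {g: np.asarray(fit.sigma_re, dtype=float) for g in GROUPS}
    else:
        covs = {g: _group_sampling_cov(fit, g) for g in GROUPS}

    template = fit.model.bundle
    group_codes = np.concatenate(
        [np.zeros(group_sizes[0]), np.ones(group_sizes[1])]
    )
    point = group_thresholds(fit, criterion)

    draws: dict[str, list[float]] = {g: [] for g in GROUPS}
    n_dropped = 0
    fix = np.zeros((2, 2)) if refit_sigma == "zero" else None
    for _ in range(n_samples):
        obs = np.vstack(
            [
                rng.multivariate_normal(means[g], covs[g], size=n, method="svd")
                for g, n in zip(GROUPS, group_sizes)
            ]
        )
        bundle = _simulate_refit_bundle(obs, group_codes, design, rng, template)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = ProbitGLMM(bundle)
            refit = model.fit(
                n_quad=n_quad,
                fix_sigma=fix,
                start_beta=fit.beta,
                start_sigma=None if fix is not None else np.asarray(fit.sigma_re),
                compute_cov=False,
            )
        if not refit.converged:
            n_dropped += 1
            continue
        try:
            th = group_thresholds(refit, criterion)
        except ValidationError:
            n_dropped += 1
            continue
        for g in GROUPS:
            draws[g].append(th[g])

    if n_dropped > max_dropped_frac * n_samples:
        raise ConvergenceError(
            f"{n_dropped}/{n_samples} bootstrap refits failed to converge; "
            "consider more data per observer or Laplace refits (n_quad=1)"
        )
    arrays = {g: np.asarray(v) for g, v in draws.items()}
    return BootstrapSummary(
        n_samples=n_samples,
        thresholds=arrays,
        sd={g: float(np.std(v, ddof=1)) for g, v in arrays.items()},
        point=point,
        n_dropped=n_dropped,
        criterion=criterion,
        seed=seed,
        covariance_mode=covariance_mode,
    )


def compare_group_thresholds(summary: BootstrapSummary) -> float:
    """Two-sided bootstrap p for a group threshold difference.

    ``p = 2 * min(Pr(diff <= 0), Pr(diff >= 0))`` over the bootstrap draws,
    with the (k+1)/(B+1) continuity correction, so p is never exactly 0;
    capped at 1.
    """
    diff = summary.difference_draws()
    B = diff.size
    if B == 0:
        raise ValidationError("no bootstrap draws available")
    k_low = int(np.sum(diff <= 0))
    k_high = int(np.sum(diff >= 0))
    p = 2.0 * (min(k_low, k_high) + 1) / (B + 1)
    return float(min(p, 1.0))
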