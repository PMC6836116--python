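"""Synthetic observers and 2AFC trial data.

The generative model mirrors the parametric-bootstrap recipe used to analyse
the study: each observer carries a probit-scale intercept and contrast slope,

    P(correct | contrast c) = Phi(intercept + slope * c),

with the per-observer ``(intercept, slope)`` pair equal to that observer's
group-level fixed effects plus a zero-mean bivariate normal deviation with
covariance ``sigma_re``.  Trial outcomes are independent Bernoulli draws.

There is no lapse or guessing parameter: chance behaviour corresponds to a
linear predictor of 0 (Phi(0) = 0.5), matching the probit-link analysis model
rather than a 0.5-floored psychometric function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .design import BASELINE, SessionDesign, format_condition

CONTROL = "control"
MIGRAINE_AURA = "migraine_aura"
GROUPS = (CONTROL, MIGRAINE_AURA)

#: Columns of a trial table, in canonical order.
TRIAL_COLUMNS = ("observer_id", "group", "condition", "contrast", "correct")

#: Generative defaults: probit intercept, contrast slope (per unit Michelson
#: proportion), group offset, and group x contrast offset for the
#: migraine-with-aura group.  Slope terms follow the study's fitted baseline
#: coefficients; the intercept places the control 75% threshold near the
#: middle of the contrast range.
DEFAULT_BETA = (-0.5, 29.141, -0.391, 12.313)

#: Default random-effects covariance of per-observer (intercept, slope).
DEFAULT_SIGMA_RE = ((0.04, 0.0), (0.0, 16.0))

#: Study group sizes: 31 controls, 24 migraine-with-aura.
DEFAULT_GROUP_SIZES = (31, 24)


class ValidationError(ValueError):
    """Invalid inputs to the simulation or analysis pipeline."""


@dataclass(frozen=True)
class ObserverParams:
    """One simulated observer's psychometric parameters (probit scale)."""

    observer_id: str
    group: str
    intercept: float
    contrast_slope: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not np.isfinite(self.intercept) or not np.isfinite(self.contrast_slope):
            raise ValidationError("observer parameters must be finite")

    def p_correct(self, contrast: float, condition_offset: float = 0.0) -> float:
        """Phi(intercept + offset + slope * contrast)."""
        eta = self.intercept + condition_offset + self.contrast_slope * contrast
        if not np.isfinite(eta):
            raise ValidationError(f"non-finite linear predictor for {self.observer_id}")
        return float(ndtr(eta))


@dataclass(frozen=True)
class PopulationParams:
    """Generative population: fixed effects plus observer heterogeneity.

    Parameters
    ----------
    beta
        ``(intercept, contrast_slope, group_offset, group_x_contrast_offset)``
        with the control group as reference; the two offsets apply to the
        migraine-with-aura group.
    sigma_re
        2x2 covariance of per-observer (intercept, slope) deviations;
        symmetric positive semi-definite.
    group_sizes
        ``(n_control, n_migraine_aura)``.
    condition_offsets
        Optional probit-scale intercept offsets per condition token, used to
        seed lateral-interaction scenarios (a positive offset lowers the
        detection threshold in that condition, i.e. facilitation).  Conditions
        not listed get offset 0; the baseline offset defaults to 0.
    """

    beta: tuple[float, float, float, float] = DEFAULT_BETA
    sigma_re: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_SIGMA_RE
    group_sizes: tuple[int, int] = DEFAULT_GROUP_SIZES
    condition_offsets: dict | None = None

    def __post_init__(self) -> None:
        beta = tuple(float(b) for b in self.beta)
        if len(beta) != 4 or not all(np.isfinite(beta)):
            raise ValidationError("beta must be 4 finite fixed effects")
        object.__setattr__(self, "beta", beta)
        sig = np.asarray(self.sigma_re, dtype=float)
        _check_psd(sig, "sigma_re")
        object.__setattr__(self, "sigma_re", tuple(map(tuple, sig)))
        sizes = tuple(int(n) for n in self.group_sizes)
        if len(sizes) != 2 or any(n < 1 for n in sizes):
            raise ValidationError("group_sizes must be two positive counts")
        object.__setattr__(self, "group_sizes", sizes)

    def group_means(self, group: str) -> tuple[float, float]:
        """Fixed-effect (intercept, slope) for one group."""
        b0, b1, b2, b3 = self.beta
        if group == CONTROL:
            return (b0, b1)
        if group == MIGRAINE_AURA:
            return (b0 + b2, b1 + b3)
        raise ValidationError(f"unknown group {group!r}")

    def condition_offset(self, condition: str) -> float:
        if not self.condition_offsets:
            return 0.0
        return float(self.condition_offsets.get(condition, 0.0))


def _check_psd(sigma: np.ndarray, name: str) -> None:
    if sigma.shape != (2, 2):
        raise ValidationError(f"{name} must be 2x2, got shape {sigma.shape}")
    if not np.allclose(sigma, sigma.T):
        raise ValidationError(f"{name} is not symmetric:\n{sigma}")
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
        raise ValidationError(f"{name} is not positive semi-definite:\n{sigma}")


def draw_observers(pop: PopulationParams, seed: int) -> list[ObserverParams]:
    """Draw a population of simulated observers.

    Each observer's (intercept, slope) is its group's fixed effects plus a
    zero-mean bivariate normal deviation with covariance ``pop.sigma_re``.
    Observer ids are ``C01..`` for controls and ``M01..`` for the
    migraine-with-aura group.
    """
    rng = np.random.default_rng(seed)
    sigma = np.asarray(pop.sigma_re, dtype=float)
    observers: list[ObserverParams] = []
    for group, n, prefix in zip(GROUPS, pop.group_sizes, ("C", "M")):
        mean = pop.group_means(group)
        draws = rng.multivariate_normal(mean, sigma, size=n, method="svd")
        width = max(2, len(str(n)))
        for i, (b0, b1) in enumerate(draws, start=1):
            observers.append(
                ObserverParams(f"{prefix}{i:0{width}d}", group, float(b0), float(b1))
            )
    return observers


def simulate_trials(
    obs: ObserverParams,
    design: SessionDesign,
    condition: str,
    seed,
    condition_offset: float = 0.0,
) -> pd.DataFrame:
    """Simulate one block: every contrast level x ``reps_per_level`` trials.

    Success probability at contrast ``c`` is
    ``Phi(intercept + condition_offset + slope * c)``; trial order is
    randomised within the block, as contrast levels were in the experiment.
    """
    if condition not in design.conditions:
        raise ValidationError(
            f"condition {condition!r} not in design conditions {design.conditions}"
        )
    rng = np.random.default_rng(seed)
    levels = np.repeat(design.contrast_levels, design.reps_per_level)
    rng.shuffle(levels)
    p = np.array([obs.p_correct(c, condition_offset) for c in design.contrast_levels])
    p_by_level = dict(zip(design.contrast_levels, p))
    probs = np.array([p_by_level[c] for c in levels])
    correct = (rng.random(levels.size) < probs).astype(np.int64)
    return pd.DataFrame(
        {
            "observer_id": obs.observer_id,
            "group": obs.group,
            "condition": condition,
            "contrast": levels,
            "correct": correct,
        },
        columns=list(TRIAL_COLUMNS),
    )


def simulate_session(
    obs: ObserverParams,
    design: SessionDesign,
    seed,
    pop: PopulationParams | None = None,
) -> pd.DataFrame:
    """All blocks of one observer's session, one block per condition."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(design.n_blocks)
    blocks = []
    for child, condition in zip(children, design.conditions):
        offset = pop.condition_offset(condition) if pop is not None else 0.0
        blocks.append(simulate_trials(obs, design, condition, child, offset))
    return pd.concat(blocks, ignore_index=True)


def simulate_dataset(
    pop: PopulationParams, design: SessionDesign, seed: int
) -> pd.DataFrame:
    """Full factorial trial table: every observer x every condition block.

    The master seed is split into independent per-observer streams (and,
    within each, per-block streams), so any observer's data can be regenerated
    without simulating the rest.
    """
    master = np.random.SeedSequence(seed)
    obs_seed, draw_seed = master.spawn(2)
    observers = draw_observers(pop, draw_seed)
    tables = [
        simulate_session(obs, design, child, pop)
        for obs, child in zip(observers, obs_seed.spawn(len(observers)))
    ]
    return pd.concat(tables, ignore_index=True)
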