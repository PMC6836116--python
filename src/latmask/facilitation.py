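"""Baseline-normalised lateral-interaction profiles.

Flanker-condition thresholds are divided by the same group's no-flanker
baseline threshold: relative values below 1 indicate facilitation by the
collinear flankers, values above 1 indicate inhibition (masking).
Normalisation is always within group — each group is scaled by its own
baseline — so a group difference in absolute sensitivity does not masquerade
as a lateral-interaction difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BASELINE, SessionDesign, condition_distance
from .model import baseline_spec, flanker_spec, ProbitGLMM
from .simulate import CONTROL, GROUPS, MIGRAINE_AURA, ValidationError
from .thresholds import ThresholdEstimate, bootstrap_threshold_sd, group_thresholds

__all__ = [
    "RelativeThreshold",
    "classify_interaction",
    "normalize_thresholds",
    "facilitation_profile",
]

FACILITATION = "facilitation"
INHIBITION = "inhibition"
NONE = "none"


@dataclass(frozen=True)
class RelativeThreshold:
    """A flanker-condition threshold expressed relative to baseline."""

    group: str
    flanker_distance: float
    relative_value: float
    classification: str
    sd: float | None = None


def classify_interaction(relative_value: float, tolerance: float = 0.0) -> str:
    """'inhibition' above 1+tolerance, 'facilitation' below 1-tolerance."""
    if relative_value <= 0:
        raise ValidationError("relative threshold must be positive")
    if tolerance < 0:
        raise ValidationError("tolerance must be non-negative")
    if relative_value > 1.0 + tolerance:
        return INHIBITION
    if relative_value < 1.0 - tolerance:
        return FACILITATION
    return NONE


def normalize_thresholds(
    condition_thresholds: list[ThresholdEstimate],
    baseline: ThresholdEstimate,
    tolerance: float = 0.0,
) -> list[RelativeThreshold]:
    """Divide each condition threshold by the group's baseline threshold."""
    if baseline.threshold <= 0:
        raise ValidationError(f"baseline threshold must be positive, got {baseline.threshold}")
    out = []
    for est in condition_thresholds:
        if est.group != baseline.group:
            raise ValidationError(
                f"group mismatch: condition {est.group!r} vs baseline {baseline.group!r}"
            )
        dist = condition_distance(est.condition)
        if dist is None:
            raise ValidationError("baseline condition cannot be normalised against itself")
        rel = est.threshold / baseline.threshold
        if est.sd is None:
            sd = None
        elif baseline.sd is None:
            sd = est.sd / baseline.threshold
        else:
            # first-order error propagation for the ratio
            sd = rel * float(
                np.hypot(est.sd / est.threshold, baseline.sd / baseline.threshold)
            )
        out.append(
            RelativeThreshold(
                group=est.group,
                flanker_distance=dist,
                relative_value=rel,
                classification=classify_interaction(rel, tolerance),
                sd=sd,
            )
        )
    return out


def _per_condition_thresholds(
    trials: pd.DataFrame,
    design: SessionDesign,
    criterion: float,
    bootstrap_samples: int,
    seed: int,
    fit_kwargs: dict,
    bootstrap_kwargs: dict,
) -> dict[str, dict[str, ThresholdEstimate]]:
    """Fit the baseline-type model separately in each condition block."""
    conditions = list(dict.fromkeys(trials["condition"]))
    group_sizes = tuple(
        trials.loc[trials["group"] == g, "observer_id"].nunique() for g in GROUPS
    )
    spec = baseline_spec()
    seeds = np.random.SeedSequence(seed).spawn(len(conditions))
    out: dict[str, dict[str, ThresholdEstimate]] = {g: {} for g in GROUPS}
    for cond, cond_seed in zip(conditions, seeds):
        block = trials[trials["condition"] == cond]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            fit = ProbitGLMM.from_trials(block, spec).fit(**fit_kwargs)
        if not fit.converged:
            raise ValidationError(f"per-condition fit did not converge for {cond!r}")
        th = group_thresholds(fit, criterion)
        sds: dict[str, float | None] = {g: None for g in GROUPS}
        if bootstrap_samples:
            summary = bootstrap_threshold_sd(
                fit,
                group_sizes,
                design,
                n_samples=bootstrap_samples,
                seed=int(cond_seed.generate_state(1)[0] % (2**31)),
                criterion=criterion,
                **bootstrap_kwargs,
            )
            sds = dict(summary.sd)
        for g in GROUPS:
            out[g][cond] = ThresholdEstimate(g, cond, th[g], criterion, sds[g])
    return out


def facilitation_profile(
    trials: pd.DataFrame,
    design: SessionDesign | None = None,
    mode: str = "per_condition",
    criterion: float = 0.75,
    tolerance: float = 0.0,
    bootstrap_samples: int = 0,
    seed: int = 0,
    fit_kwargs: dict | None = None,
    bootstrap_kwargs: dict | None = None,
) -> pd.DataFrame:
    """End-to-end relative-threshold profile from a trial table.

    ``mode='per_condition'`` (default) fits the baseline-type model in each
    condition block separately; ``mode='joint'`` fits the single flanker
    model with distance terms and evaluates it at each distance (the baseline
    threshold still comes from a baseline-block fit).  Bootstrap SDs, if
    requested, are combined by first-order error propagation of the
    condition/baseline ratio (condition and baseline draws are independent
    bootstrap runs, not paired).

    Returns a frame with columns
    ``group, distance_lambda, relative_threshold, sd, classification``.
    """
    if BASELINE not in set(trials["condition"]):
        raise ValidationError("trial table has no baseline (no-flanker) block")
    if not set(trials["condition"]) - {BASELINE}:
        raise ValidationError("trial table has no flanker condition blocks")
    if design is None:
        design = SessionDesign()
    fit_kwargs = dict(fit_kwargs or {})
    bootstrap_kwargs = dict(bootstrap_kwargs or {})

    rows = []
    if mode == "per_condition":
        per_cond = _per_condition_thresholds(
            trials, design, criterion, bootstrap_samples, seed, fit_kwargs, bootstrap_kwargs
        )
        for g in GROUPS:
            baseline = per_cond[g].pop(BASELINE)
            conds = sorted(per_cond[g].values(), key=lambda e: condition_distance(e.condition))
            rows.extend(normalize_thresholds(conds, baseline, tolerance))
    elif mode == "joint":
        distances = sorted(
            {condition_distance(c) for c in trials["condition"]} - {None}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            joint = ProbitGLMM.from_trials(trials, flanker_spec()).fit(**fit_kwargs)
            base_fit = ProbitGLMM.from_trials(
                trials[trials["condition"] == BASELINE], baseline_spec()
            ).fit(**fit_kwargs)
        if not (joint.converged and base_fit.converged):
            raise ValidationError("joint-mode fits did not converge")
        for g in GROUPS:
            base_th = group_thresholds(base_fit, criterion)[g]
            ests = [
                ThresholdEstimate(
                    g, str(int(d) if float(d).is_integer() else d),
                    group_thresholds(joint, criterion, distance=d)[g], criterion
                )
                for d in distances
            ]
            baseline = ThresholdEstimate(g, BASELINE, base_th, criterion)
            rows.extend(normalize_thresholds(ests, baseline, tolerance))
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    return pd.DataFrame(
        {
            "group": [r.group for r in rows],
            "distance_lambda": [r.flanker_distance for r in rows],
            "relative_threshold": [r.relative_value for r in rows],
            "sd": [r.sd for r in rows],
            "classification": [r.classification for r in rows],
        }
    ).sort_values(["group", "distance_lambda"], ignore_index=True)


def plot_profile(profile: pd.DataFrame, ax=None):
    """Relative thresholds vs flanker distance with a unity reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for g, marker in zip(GROUPS, ("o", "s")):
        sub = profile[profile["group"] == g]
        if sub.empty:
            continue
        yerr = sub["sd"] if sub["sd"].notna().all() else None
        ax.errorbar(
            sub["distance_lambda"], sub["relative_threshold"], yerr=yerr,
            marker=marker, capsize=3, label=g.replace("_", "-"),
        )
    ax.axhline(1.0, color="k", lw=1)
    ax.set_xlabel("flanker distance (wavelengths)")
    ax.set_ylabel("relative 75% threshold")
    ax.legend()
    return ax
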