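"""Session design for the 2AFC lateral-masking experiment.

A session is organised in blocks, one per flanker condition: six collinear
flanker distances (in wavelengths of the Gabor carrier) plus an optional
no-flanker baseline.  Within each block every target contrast level is
repeated a fixed number of times, giving ``levels x reps`` trials per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BASELINE = "baseline"

#: The seven Michelson-contrast levels of the study, as proportions.
PAPER_CONTRAST_LEVELS = (0.0075, 0.015, 0.0225, 0.03, 0.045, 0.06, 0.09)

#: Collinear flanker distances in carrier wavelengths.
PAPER_FLANKER_DISTANCES = (1, 2, 3, 4, 6, 12)


@dataclass(frozen=True)
class SessionDesign:
    """Factorial layout of one observer's session.

    Parameters
    ----------
    contrast_levels
        Michelson contrasts of the target, proportions in (0, 1], strictly
        increasing.
    reps_per_level
        Repetitions of each contrast level within a block.
    flanker_distances
        Centre-to-centre target/flanker separations in carrier wavelengths.
    include_baseline
        Whether a no-flanker block is part of the session.
    n_intervals
        Number of intervals of the forced choice (2 for 2AFC); chance
        performance is ``1 / n_intervals``.
    """

    contrast_levels: tuple[float, ...] = PAPER_CONTRAST_LEVELS
    reps_per_level: int = 20
    flanker_distances: tuple[float, ...] = PAPER_FLANKER_DISTANCES
    include_baseline: bool = True
    n_intervals: int = 2

    def __post_init__(self) -> None:
        levels = tuple(float(c) for c in self.contrast_levels)
        object.__setattr__(self, "contrast_levels", levels)
        object.__setattr__(
            self, "flanker_distances", tuple(float(d) for d in self.flanker_distances)
        )
        if not levels:
            raise ValueError("at least one contrast level is required")
        if any(not (0.0 < c <= 1.0) for c in levels):
            raise ValueError(f"contrast levels must lie in (0, 1]: {levels}")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError(f"contrast levels must be strictly increasing: {levels}")
        if self.reps_per_level < 1:
            raise ValueError("reps_per_level must be >= 1")
        if any(d <= 0 for d in self.flanker_distances):
            raise ValueError(f"flanker distances must be positive: {self.flanker_distances}")
        if self.n_intervals < 2:
            raise ValueError("a forced choice needs at least 2 intervals")

    @property
    def conditions(self) -> tuple[str, ...]:
        """Condition tokens: ``'baseline'`` (if included) then distances."""
        conds = tuple(format_condition(d) for d in self.flanker_distances)
        return ((BASELINE,) if self.include_baseline else ()) + conds

    @property
    def n_blocks(self) -> int:
        return len(self.conditions)

    @property
    def trials_per_block(self) -> int:
        return len(self.contrast_levels) * self.reps_per_level

    @property
    def trials_per_session(self) -> int:
        return self.n_blocks * self.trials_per_block


def format_condition(distance: float) -> str:
    """Token for a flanker condition: integer distances print without decimals."""
    d = float(distance)
    return str(int(d)) if d.is_integer() else repr(d)


def condition_distance(condition: str) -> float | None:
    """Flanker distance in wavelengths, or ``None`` for the baseline token."""
    if condition == BASELINE:
        return None
    try:
        return float(condition)
    except ValueError:
        raise ValueError(f"unknown condition token: {condition!r}") from None
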