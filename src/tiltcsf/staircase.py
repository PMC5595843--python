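"""Weighted up-down adaptive staircase engine.

A weighted (Kaernbach-style) up-down rule moves the stimulus level down
by ``down_step`` after the tracked response and up by ``up_step``
otherwise.  At equilibrium the tracked-response probability satisfies
``p * down_step = (1 - p) * up_step``, i.e. the staircase converges to
``p = up_step / (up_step + down_step)``.  Steps Up/Down of 2/5 and 5/2
degrees therefore track the ~29% and ~71% points of an orientation
psychometric function; the detection staircases use log-contrast steps
expressed as multiples of the base 10%-contrast log-unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StaircaseConfig", "WeightedUpDown", "BASE_LOG_STEP"]

#: One "base 10% contrast" step in log10-contrast units.
BASE_LOG_STEP = float(np.log10(1.1))


@dataclass(frozen=True)
class StaircaseConfig:
    """Static description of one staircase track.

    Steps are in the native units of the tracked level (degrees for
    tilt, log10-contrast for detection).  ``down_boost`` multiplies the
    down step for the first ``boost_trials`` trials (used by the
    detection staircases to leave a deliberately high or low starting
    contrast quickly).
    """

    up_step: float
    down_step: float
    start_level: float
    n_trials: int
    down_boost: float = 1.0
    boost_trials: int = 0
    min_level: float | None = None
    max_level: float | None = None

    def __post_init__(self) -> None:
        if self.up_step <= 0 or self.down_step <= 0:
            raise ValueError("step sizes must be positive")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")

    @property
    def convergence_probability(self) -> float:
        """Tracked-response probability at the equilibrium level."""
        return self.up_step / (self.up_step + self.down_step)


class WeightedUpDown:
    """Mutable staircase state; one instance per track."""

    def __init__(self, config: StaircaseConfig):
        self.config = config
        self.level = float(config.start_level)
        self.trial_count = 0
        self.history: list[float] = []

    def update(self, tracked_response: bool) -> None:
        """Advance one trial: record the level just tested, then step
        down after the tracked response, up otherwise."""
        cfg = self.config
        self.history.append(self.level)
        down = cfg.down_step
        if self.trial_count < cfg.boost_trials:
            down *= cfg.down_boost
        self.level += -down if tracked_response else cfg.up_step
        if cfg.min_level is not None:
            self.level = max(self.level, cfg.min_level)
        if cfg.max_level is not None:
            self.level = min(self.level, cfg.max_level)
        self.trial_count += 1

    @property
    def done(self) -> bool:
        return self.trial_count >= self.config.n_trials
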