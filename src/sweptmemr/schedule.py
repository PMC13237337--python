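"""Stimulus timelines for the swept and discrete MEMR elicitor paradigms.

The swept paradigm runs a 20/s probe-click train in one ear while a
contralateral broadband noise elicitor sweeps linearly from ``level_min``
up to ``level_max`` and back (a level triangle), 160 clicks per 8-s sweep
at the defaults, repeated 15 times.  The discrete paradigm presents
click – 500-ms noise burst – click sequences at fixed levels stepped up
and then down, 12 repetitions per level.

Schedules are deterministic; levels are nominal dB FPL (no calibration
transfer is modelled).  The first click coincides with sweep onset, and a
click falling exactly at the ramp apex is assigned the peak level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SweptScheduleSpec",
    "DiscreteScheduleSpec",
    "elicitor_level_at_time",
    "click_schedule",
    "discrete_schedule",
]


@dataclass(frozen=True)
class SweptScheduleSpec:
    """Parameters of the swept (triangular) elicitor paradigm.

    Attributes
    ----------
    level_min, level_max : float
        Elicitor sweep endpoints, dB FPL.
    ramp_duration : float
        Duration of each ramp direction, s; a full sweep lasts twice this.
    click_rate : float
        Probe click rate, clicks/s.
    click_level : float
        Probe click level, dB pFPL (metadata only; clicks are not scaled).
    n_sweeps : int
        Number of sweep repetitions in one test.
    """

    level_min: float = 40.0
    level_max: float = 110.0
    ramp_duration: float = 4.0
    click_rate: float = 20.0
    click_level: float = 96.0
    n_sweeps: int = 15

    def __post_init__(self) -> None:
        if not self.level_max > self.level_min:
            raise ValueError("level_max must exceed level_min")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be positive")
        if self.click_rate <= 0:
            raise ValueError("click_rate must be positive")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")

    @property
    def sweep_duration(self) -> float:
        return 2.0 * self.ramp_duration

    @property
    def clicks_per_sweep(self) -> int:
        return int(round(self.sweep_duration * self.click_rate))

    @property
    def sweep_rate(self) -> float:
        """Level change rate on either ramp, dB/s."""
        return (self.level_max - self.level_min) / self.ramp_duration


def _default_ascending() -> tuple[float, ...]:
    return tuple(np.arange(37.5, 92.5 + 1e-9, 5.0))


def _default_descending() -> tuple[float, ...]:
    return tuple(np.arange(90.0, 35.0 - 1e-9, -5.0))


@dataclass(frozen=True)
class DiscreteScheduleSpec:
    """Parameters of the discrete (click–burst–click) elicitor paradigm."""

    ascending_levels: tuple[float, ...] = field(default_factory=_default_ascending)
    descending_levels: tuple[float, ...] = field(default_factory=_default_descending)
    burst_duration: float = 0.5
    reps_per_level: int = 12
    inter_sequence_silence: float = 1.0
    pre_burst_gap: float = 0.05
    post_burst_gap: float = 0.05

    def __post_init__(self) -> None:
        levels = np.asarray(self.ascending_levels + self.descending_levels, dtype=float)
        if levels.size == 0 or not np.all(np.isfinite(levels)):
            raise ValueError("elicitor levels must be finite and non-empty")
        if self.reps_per_level < 1:
            raise ValueError("reps_per_level must be >= 1")
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be positive")

    @property
    def n_sequences(self) -> int:
        return self.reps_per_level * (
            len(self.ascending_levels) + len(self.descending_levels)
        )

    @property
    def sequence_duration(self) -> float:
        """Span from click1 to click2 plus the following silence."""
        return (
            self.pre_burst_gap
            + self.burst_duration
            + self.post_burst_gap
            + self.inter_sequence_silence
        )


def elicitor_level_at_time(spec: SweptScheduleSpec, t):
    """Elicitor level (dB FPL) at time ``t`` (s) within one sweep.

    The level is a piecewise-linear triangle: rising from ``level_min`` at
    t=0 to ``level_max`` at t=ramp_duration, then falling back.  Accepts a
    scalar or array; raises ``ValueError`` outside [0, 2*ramp_duration].
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > spec.sweep_duration):
        raise ValueError(
            f"time outside sweep support [0, {spec.sweep_duration}] s"
        )
    rate = spec.sweep_rate
    level = np.where(
        t_arr <= spec.ramp_duration,
        spec.level_min + rate * t_arr,
        spec.level_max - rate * (t_arr - spec.ramp_duration),
    )
    return float(level) if np.isscalar(t) else level


def click_schedule(spec: SweptScheduleSpec) -> pd.DataFrame:
    """Full click timeline for a swept test.

    Returns a DataFrame with columns ``sweep``, ``click_index``, ``time_s``
    (absolute session time), ``time_in_sweep_s`` and ``elicitor_db_fpl``.
    Clicks are equally spaced at 1/click_rate starting at sweep onset.
    """
    n_clicks = spec.clicks_per_sweep
    t_in_sweep = np.arange(n_clicks) / spec.click_rate
    levels = elicitor_level_at_time(spec, t_in_sweep)
    rows = []
    for sweep in range(spec.n_sweeps):
        rows.append(
            pd.DataFrame(
                {
                    "sweep": sweep,
                    "click_index": np.arange(n_clicks),
                    "time_s": sweep * spec.sweep_duration + t_in_sweep,
                    "time_in_sweep_s": t_in_sweep,
                    "elicitor_db_fpl": levels,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def discrete_schedule(spec: DiscreteScheduleSpec) -> pd.DataFrame:
    """Sequence timeline for a discrete test.

    One row per (level, repetition) sequence, in presentation order:
    all repetitions of each ascending level, then of each descending level.
    Columns: ``sequence_index``, ``phase`` ("ascending"/"descending"),
    ``level_db_fpl``, ``click1_time_s``, ``burst_onset_s``, ``click2_time_s``.
    """
    rows = []
    t = 0.0
    seq = 0
    for phase, levels in (
        ("ascending", spec.ascending_levels),
        ("descending", spec.descending_levels),
    ):
        for level in levels:
            for _ in range(spec.reps_per_level):
                click1 = t
                burst_onset = click1 + spec.pre_burst_gap
                click2 = burst_onset + spec.burst_duration + spec.post_burst_gap
                rows.append(
                    {
                        "sequence_index": seq,
                        "phase": phase,
                        "level_db_fpl": float(level),
                        "click1_time_s": click1,
                        "burst_onset_s": burst_onset,
                        "click2_time_s": click2,
                    }
                )
                t = click2 + spec.inter_sequence_silence
                seq += 1
    return pd.DataFrame(rows)
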