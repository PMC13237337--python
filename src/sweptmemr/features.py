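"""Summary measures of total-change level-growth functions.

A swept-paradigm LGF is summarized by five measures: maximum total change
(dB re baseline), reflex delay (time of the TC peak minus the time the
elicitor peaked), onset and offset thresholds (elicitor level at which TC
crosses −12 dB re its maximum — a 74.9% amplitude reduction — on the
ascending/descending limb, after compensating the delay), and hysteresis
(offset minus onset; negative when the reflex persists at lower levels on
the way down).  Discrete-paradigm level series are reduced to one total
change per elicitor level for comparison with the swept LGF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import TotalChangeLGF, total_change_db
from .preprocess import BinnedResponseMatrix
from .schedule import DiscreteScheduleSpec, SweptScheduleSpec, discrete_schedule

__all__ = [
    "CRITERION_DB",
    "ReflexFeatures",
    "criterion_fraction",
    "extract_features",
    "discrete_lgf",
    "swept_vs_discrete_difference",
]

#: threshold criterion re maximum total change (amplitude ratio in dB)
CRITERION_DB = -12.0


@dataclass
class ReflexFeatures:
    """The five LGF summary measures for one test.

    Absent thresholds (LGF never crosses the criterion) are NaN with a
    flag; hysteresis is defined only when both thresholds are present.
    """

    max_total_change_db: float
    reflex_delay_s: float
    onset_threshold_db: float
    offset_threshold_db: float
    hysteresis_db: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "max_tc_db": self.max_total_change_db,
            "delay_ms": self.reflex_delay_s * 1e3,
            "onset_db": self.onset_threshold_db,
            "offset_db": self.offset_threshold_db,
            "hysteresis_db": self.hysteresis_db,
            "flags": ";".join(self.flags),
        }


def criterion_fraction(threshold_db: float = CRITERION_DB) -> float:
    """Fractional amplitude reduction at a dB criterion (−12 dB → 0.749)."""
    if threshold_db > 0:
        raise ValueError("criterion must be <= 0 dB")
    return 1.0 - 10.0 ** (threshold_db / 20.0)


def _interp_crossing(l0, l1, tc0, tc1, crit):
    f = (crit - tc0) / (tc1 - tc0)
    return float(l0 + f * (l1 - l0))


def extract_features(
    lgf: TotalChangeLGF,
    schedule: SweptScheduleSpec,
    criterion_db: float = CRITERION_DB,
) -> ReflexFeatures:
    """Extract the five summary measures from one swept LGF.

    The peak (first index on ties) gives the maximum total change and,
    relative to the ramp apex, the reflex delay.  The time axis is then
    shifted by −delay, mapped back to elicitor levels (clamped to the
    sweep support), and the criterion level 10^(criterion/20)·TC(peak) is
    located by linear interpolation: last upward crossing before the peak
    (onset) and first downward crossing after it (offset), which makes the
    estimates robust to sub-threshold noise wiggles.
    """
    tc = np.asarray(lgf.tc, dtype=float)
    t = np.asarray(lgf.time_s, dtype=float)
    n = tc.size
    peak = int(np.argmax(tc))
    max_db = float(total_change_db(tc[peak]))
    delay = float(t[peak] - schedule.ramp_duration)
    flags: list[str] = []
    if peak in (0, n - 1):
        flags.append("delay_unreliable")
    # delay-compensated elicitor level per click
    t_shift = np.clip(t - delay, 0.0, schedule.sweep_duration)
    apex = schedule.ramp_duration
    rate = schedule.sweep_rate
    levels = np.where(
        t_shift <= apex,
        schedule.level_min + rate * t_shift,
        schedule.level_max - rate * (t_shift - apex),
    )
    crit = 10.0 ** (criterion_db / 20.0) * tc[peak]
    onset = offset = float("nan")
    for i in range(peak, 0, -1):
        if tc[i - 1] < crit <= tc[i]:
            onset = _interp_crossing(levels[i - 1], levels[i], tc[i - 1], tc[i], crit)
            break
    for i in range(peak, n - 1):
        if tc[i] >= crit > tc[i + 1]:
            offset = _interp_crossing(levels[i], levels[i + 1], tc[i], tc[i + 1], crit)
            break
    if np.isnan(onset):
        flags.append("onset_absent")
    if np.isnan(offset):
        flags.append("offset_absent")
    hysteresis = offset - onset if not (np.isnan(onset) or np.isnan(offset)) else float("nan")
    return ReflexFeatures(
        max_total_change_db=max_db,
        reflex_delay_s=delay,
        onset_threshold_db=onset,
        offset_threshold_db=offset,
        hysteresis_db=hysteresis,
        flags=flags,
    )


def discrete_lgf(
    matrix: BinnedResponseMatrix, spec: DiscreteScheduleSpec
) -> pd.DataFrame:
    """Level-indexed total change from a discrete (click–burst–click) test.

    Per sequence the complex ratio click2/click1 is formed per bin; ratios
    are averaged across the repetitions of each level, total change of the
    mean ratio is computed per bin and averaged across bins.  Ascending
    and descending tracks are kept separate.  Sequences with a missing
    click are dropped with a warning.
    """
    import warnings

    sched = discrete_schedule(spec)
    if len(sched) != matrix.n_groups or matrix.n_clicks != 2:
        raise ValueError("matrix does not match the discrete schedule")
    v = matrix.values
    usable = ~matrix.flags.any(axis=1)
    tiny = 1e-12 * max(np.abs(v).max(), 1.0)
    paired = np.abs(v[:, 0, :]).min(axis=1) > tiny
    keep = usable & paired
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} unpaired/flagged sequences")
    ratios = np.full((matrix.n_groups, v.shape[2]), np.nan, dtype=complex)
    ratios[keep] = v[keep, 1, :] / v[keep, 0, :]
    rows = []
    for (phase, level), grp in sched.groupby(["phase", "level_db_fpl"], sort=False):
        idx = grp.index.to_numpy()
        idx = idx[keep[idx]]
        if idx.size == 0:
            continue
        mean_ratio = ratios[idx].mean(axis=0)
        tc = float(np.abs(mean_ratio - 1.0).mean())
        rows.append(
            {
                "phase": phase,
                "level_db_fpl": float(level),
                "tc": tc,
                "tc_db": float(total_change_db(tc)),
                "n_reps": int(idx.size),
            }
        )
    return pd.DataFrame(rows)


def swept_vs_discrete_difference(
    lgf: TotalChangeLGF,
    features: ReflexFeatures,
    discrete: pd.DataFrame,
    schedule: SweptScheduleSpec,
) -> pd.DataFrame:
    """Per-level dB differences, swept minus discrete, at comparable levels.

    The swept LGF is delay-compensated and sampled (by interpolation in
    level) on its ascending limb at discrete ascending levels at or above
    the onset threshold, and on its descending limb at discrete descending
    levels at or above the offset threshold.  Returns one row per compared
    level plus ``mean``/``sd`` in ``DataFrame.attrs``.
    """
    import warnings

    tc = np.asarray(lgf.tc, float)
    t = np.asarray(lgf.time_s, float)
    peak = int(np.argmax(tc))
    t_shift = np.clip(t - features.reflex_delay_s, 0.0, schedule.sweep_duration)
    apex = schedule.ramp_duration
    rate = schedule.sweep_rate
    levels = np.where(
        t_shift <= apex,
        schedule.level_min + rate * t_shift,
        schedule.level_max - rate * (t_shift - apex),
    )
    tc_db = total_change_db(tc)
    rows = []
    for _, row in discrete.iterrows():
        phase, level = row["phase"], row["level_db_fpl"]
        if phase == "ascending":
            if np.isnan(features.onset_threshold_db) or level < features.onset_threshold_db:
                continue
            seg = slice(0, peak + 1)
            x, y = levels[seg], tc_db[seg]
        else:
            if np.isnan(features.offset_threshold_db) or level < features.offset_threshold_db:
                continue
            seg = slice(peak, None)
            x, y = levels[seg][::-1], tc_db[seg][::-1]
        if level < x.min() or level > x.max():
            continue
        swept_db = float(np.interp(level, x, y))
        rows.append(
            {
                "phase": phase,
                "level_db_fpl": float(level),
                "swept_tc_db": swept_db,
                "discrete_tc_db": float(row["tc_db"]),
                "difference_db": swept_db - float(row["tc_db"]),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        warnings.warn("no overlapping levels between swept and discrete tests")
        out.attrs.update({"mean_difference_db": float("nan"), "sd_difference_db": float("nan")})
    else:
        out.attrs.update(
            {
                "mean_difference_db": float(out["difference_db"].mean()),
                "sd_difference_db": float(out["difference_db"].std(ddof=1)) if len(out) > 1 else 0.0,
            }
        )
    return out
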