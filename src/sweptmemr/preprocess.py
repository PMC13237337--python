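"""Click-level preprocessing: epoching, time windowing, and 100-Hz FFT bins.

Raw ear-canal recordings are reduced to one complex value per click and
per analysis frequency.  The analysis window starts at the click's peak
sample and lasts 1.20 ms with 0.146-ms raised-cosine onset/offset ramps,
so the incident pressure wave (which the reflex cannot affect) is largely
excluded while reflected energy — which arrives after the ~82-µs round
trip to the eardrum and rings through multiple internal reflections — is
retained.  Windowed segments are zero-padded to an integer number of
samples per 100 Hz and Fourier transformed; the eleven bins centred at
500…1500 Hz form the analysis band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedule import SweptScheduleSpec, click_schedule, discrete_schedule

__all__ = [
    "DEFAULT_FS",
    "WINDOW_DURATION_S",
    "RAMP_DURATION_S",
    "BIN_WIDTH_HZ",
    "BIN_CENTERS_HZ",
    "ClickEpoch",
    "BinnedResponseMatrix",
    "round_half_away",
    "analysis_window",
    "epoch_clicks",
    "apply_time_window",
    "bin_spectra",
    "bin_session",
]

DEFAULT_FS = 96_000
WINDOW_DURATION_S = 1.20e-3
RAMP_DURATION_S = 0.146e-3
BIN_WIDTH_HZ = 100.0
BIN_CENTERS_HZ = np.arange(500.0, 1500.0 + 1e-9, 100.0)

#: half-width of the peak search window around the nominal click time
PEAK_SEARCH_S = 2.0e-3


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (1.20 ms @ 96 kHz -> 115)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


@dataclass
class ClickEpoch:
    """One click's waveform segment with its detected peak.

    ``samples`` holds the recording from ``peak_offset`` samples before the
    peak to at least one analysis window past it; ``flagged`` marks clicks
    with no detectable peak (downstream weight 0).
    """

    samples: np.ndarray
    peak_offset: int
    sweep: int
    click: int
    flagged: bool = False


@dataclass
class BinnedResponseMatrix:
    """Complex per-click responses indexed [group, click, frequency bin].

    For the swept paradigm a group is one sweep (160 clicks at defaults);
    for the discrete paradigm a group is one click–burst–click sequence
    (2 clicks).  ``flags`` marks missing/unusable clicks.
    """

    values: np.ndarray  # complex, (n_groups, n_clicks, n_bins)
    bin_centers: np.ndarray
    time_s: np.ndarray  # (n_groups, n_clicks) absolute session time
    levels_db: np.ndarray  # (n_groups, n_clicks) elicitor level per click
    paradigm: str = "swept"
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 3:
            raise ValueError("values must be (groups, clicks, bins)")
        if self.values.shape[2] != len(self.bin_centers):
            raise ValueError("bin dimension does not match bin_centers")
        if self.flags is None:
            self.flags = np.zeros(self.values.shape[:2], dtype=bool)

    @property
    def n_groups(self) -> int:
        return self.values.shape[0]

    @property
    def n_clicks(self) -> int:
        return self.values.shape[1]


def window_length_samples(fs: float) -> tuple[int, int]:
    """(total, ramp) sample counts of the analysis window at rate ``fs``."""
    n_total = round_half_away(WINDOW_DURATION_S * fs)
    n_ramp = round_half_away(RAMP_DURATION_S * fs)
    if n_total < 4:
        raise ValueError("sampling rate too low for the analysis window")
    return n_total, n_ramp


def analysis_window(fs: float = DEFAULT_FS) -> np.ndarray:
    """Flattop (Tukey-style) window: unity plateau, raised-cosine ramps.

    The first ramp sample has weight 0 and is placed at the click peak, so
    the onset ramp removes the bulk of the incident peak energy.
    """
    n_total, n_ramp = window_length_samples(fs)
    w = np.ones(n_total)
    j = np.arange(n_ramp)
    ramp = 0.5 * (1.0 - np.cos(np.pi * j / n_ramp))
    w[:n_ramp] = ramp
    w[-n_ramp:] = ramp[::-1]
    return w


def epoch_clicks(
    recording,
    schedule,
    fs: float | None = None,
) -> list[ClickEpoch]:
    """Cut one epoch per scheduled click, locating each peak.

    Parameters
    ----------
    recording : SessionRecording or ndarray
        Full-session pressure waveform (single channel).
    schedule : SweptScheduleSpec | DiscreteScheduleSpec | DataFrame
        Scheduled click times; specs are expanded via their schedule
        functions.  A DataFrame must carry ``time_s`` click times plus
        ``sweep``/``click_index`` (or ``sequence_index`` for discrete).
    fs : float, optional
        Sampling rate; taken from the recording when it carries one.

    The peak is the maximum absolute sample within +/-2 ms of the nominal
    click time.  Clicks whose peak does not rise above the recording's
    noise floor are returned flagged.
    """
    samples = np.asarray(getattr(recording, "samples", recording), dtype=float)
    if fs is None:
        fs = getattr(recording, "fs", DEFAULT_FS)
    times, sweeps, clicks = _click_times(schedule)
    if len(times) == 0:
        raise ValueError("schedule contains no clicks")
    n_total, _ = window_length_samples(fs)
    half = int(round(PEAK_SEARCH_S * fs))
    pre = half
    post = n_total + half
    # Noise floor: a silent recording (all ~0) must flag every click.
    floor = 10.0 * np.median(np.abs(samples))
    epochs: list[ClickEpoch] = []
    for t, sweep, click in zip(times, sweeps, clicks):
        nominal = int(round(t * fs))
        lo = max(nominal - half, 0)
        hi = min(nominal + half + 1, len(samples))
        if hi <= lo:
            raise ValueError("recording does not cover the scheduled clicks")
        seg = samples[lo:hi]
        peak = lo + int(np.argmax(np.abs(seg)))
        flagged = not (np.abs(samples[peak]) > floor)
        a = max(peak - pre, 0)
        b = min(peak + post, len(samples))
        if b - peak < n_total:
            raise ValueError("recording too short to window the last click")
        epochs.append(
            ClickEpoch(
                samples=samples[a:b].copy(),
                peak_offset=peak - a,
                sweep=int(sweep),
                click=int(click),
                flagged=flagged,
            )
        )
    return epochs


def _click_times(schedule):
    import pandas as pd

    if isinstance(schedule, SweptScheduleSpec):
        schedule = click_schedule(schedule)
    elif hasattr(schedule, "ascending_levels"):
        schedule = discrete_schedule(schedule)
    if isinstance(schedule, pd.DataFrame):
        if "click1_time_s" in schedule.columns:  # discrete layout
            times, groups, clicks = [], [], []
            for _, row in schedule.iterrows():
                for j, col in enumerate(("click1_time_s", "click2_time_s")):
                    times.append(row[col])
                    groups.append(row["sequence_index"])
                    clicks.append(j)
            return np.asarray(times), np.asarray(groups), np.asarray(clicks)
        return (
            schedule["time_s"].to_numpy(),
            schedule["sweep"].to_numpy(),
            schedule["click_index"].to_numpy(),
        )
    raise TypeError("unsupported schedule type")


def apply_time_window(
    epoch: ClickEpoch,
    window_duration: float = WINDOW_DURATION_S,
    ramp_duration: float = RAMP_DURATION_S,
    fs: float = DEFAULT_FS,
) -> np.ndarray:
    """Window an epoch from its peak; returns the windowed segment.

    The returned array starts at the peak sample (local time zero, the
    phase reference shared by all clicks) and has length
    round(window_duration*fs); everything before the peak is excluded and
    the peak sample itself carries ramp weight 0.
    """
    n_total = round_half_away(window_duration * fs)
    n_ramp = round_half_away(ramp_duration * fs)
    if len(epoch.samples) - epoch.peak_offset < n_total:
        raise ValueError("epoch too short for the analysis window")
    w = np.ones(n_total)
    j = np.arange(n_ramp)
    ramp = 0.5 * (1.0 - np.cos(np.pi * j / n_ramp))
    w[:n_ramp] = ramp
    w[-n_ramp:] = ramp[::-1]
    seg = epoch.samples[epoch.peak_offset : epoch.peak_offset + n_total]
    return seg * w


def bin_spectra(
    windowed: np.ndarray,
    fs: float = DEFAULT_FS,
    bin_width: float = BIN_WIDTH_HZ,
    bin_centers: np.ndarray = BIN_CENTERS_HZ,
) -> np.ndarray:
    """Zero-pad to 1/bin_width s and return the DFT at the analysis bins.

    At 96 kHz with 100-Hz bins the padded length is 960 samples and the
    1000-Hz bin is DFT index 10.
    """
    n_pad = fs / bin_width
    if abs(n_pad - round(n_pad)) > 1e-9:
        raise ValueError("bin_width must divide fs into an integer length")
    n_pad = int(round(n_pad))
    idx = np.asarray(bin_centers, dtype=float) / bin_width
    if np.any(np.abs(idx - np.round(idx)) > 1e-9):
        raise ValueError("bin centers must sit on the padded DFT grid")
    spec = np.fft.fft(windowed, n_pad)
    return spec[np.round(idx).astype(int)]


def bin_session(
    recording,
    schedule,
    fs: float | None = None,
    bin_centers: np.ndarray = BIN_CENTERS_HZ,
) -> BinnedResponseMatrix:
    """Full waveform-to-matrix reduction: epoch, window, bin.

    Flagged (missing) clicks get value 0 and a raised flag so downstream
    weighting removes them.
    """
    if fs is None:
        fs = getattr(recording, "fs", DEFAULT_FS)
    epochs = epoch_clicks(recording, schedule, fs=fs)
    if isinstance(schedule, SweptScheduleSpec):
        sched_df = click_schedule(schedule)
        n_groups, n_clicks = schedule.n_sweeps, schedule.clicks_per_sweep
        time_s = sched_df["time_s"].to_numpy().reshape(n_groups, n_clicks)
        levels = sched_df["elicitor_db_fpl"].to_numpy().reshape(n_groups, n_clicks)
        paradigm = "swept"
    elif hasattr(schedule, "ascending_levels"):
        sched_df = discrete_schedule(schedule)
        n_groups, n_clicks = len(sched_df), 2
        time_s = sched_df[["click1_time_s", "click2_time_s"]].to_numpy()
        levels = np.repeat(sched_df[["level_db_fpl"]].to_numpy(), 2, axis=1)
        paradigm = "discrete"
    else:
        raise TypeError("bin_session requires a schedule spec")
    values = np.zeros((n_groups, n_clicks, len(bin_centers)), dtype=complex)
    flags = np.zeros((n_groups, n_clicks), dtype=bool)
    for ep in epochs:
        if ep.flagged:
            flags[ep.sweep, ep.click] = True
            continue
        win = apply_time_window(ep, fs=fs)
        values[ep.sweep, ep.click] = bin_spectra(win, fs=fs, bin_centers=bin_centers)
    return BinnedResponseMatrix(
        values=values,
        bin_centers=np.asarray(bin_centers, dtype=float),
        time_s=time_s,
        levels_db=levels,
        paradigm=paradigm,
        flags=flags,
    )
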