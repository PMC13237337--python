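"""Synthetic MEMR sessions from a resonant middle-ear model.

The middle ear is a series resonator Z(f) = r + i2πf·m + k/(i2πf) whose
stiffness k rises by up to ``dk_max`` (fractionally) when the reflex is
active, shifting the ~1-kHz resonance upward.  Ear-canal click responses
are rendered as a band-limited incident pulse plus a train of internal
reflections between probe and eardrum, each shaped by the eardrum
reflectance (Z−Zs)/(Z+Zs) and delayed by the 2·length/c round trip.  The
same 1.20-ms window + 100-Hz-bin analysis used on real recordings defines
the per-click complex response of the model, so the directly binned
simulation path and the full waveform path agree by construction.

Reflex activation follows first-order dynamics toward a logistic function
of the (neurally delayed) elicitor level, with a fast attack and a slow
release time constant; the asymmetry produces the offset-below-onset
hysteresis seen in swept-level data.  Slow measurement drift and additive
complex noise complete the session model.  All randomness derives from a
single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .preprocess import (
    BIN_CENTERS_HZ,
    DEFAULT_FS,
    BinnedResponseMatrix,
    analysis_window,
    bin_spectra,
)
from .schedule import (
    DiscreteScheduleSpec,
    SweptScheduleSpec,
    click_schedule,
    discrete_schedule,
)

__all__ = [
    "MiddleEarParams",
    "ReflexParams",
    "NoiseParams",
    "SimulationTruth",
    "eardrum_impedance",
    "relative_pressure_change",
    "reflex_activation_trajectory",
    "ClickResponseModel",
    "simulate_binned_session",
    "simulate_click_waveforms",
    "round_trip_delay",
    "draw_subject_params",
]


@dataclass(frozen=True)
class MiddleEarParams:
    """Series-resonator middle ear seen from the ear canal.

    ``mass``/``damping``/``stiffness`` are acoustic-element values in
    mutually consistent units (only ratios matter for relative changes);
    defaults place the resonance at 1000 Hz with Q = 1.5.  ``dk_max`` is
    the maximal fractional stiffness increase at full reflex activation.
    ``source_impedance`` is the probe-side (source) impedance Zs and
    ``probe_reflectance`` the broadband magnitude of the probe-tip
    reflection that sustains the multiple-internal-reflection train.
    """

    mass: float = 1.0
    damping: float = 4188.79
    stiffness: float = 39_478_418.0  # (2*pi*1000)^2
    dk_max: float = 0.4
    source_impedance: float = 8377.58  # 2 * damping
    probe_reflectance: float = 0.5

    def __post_init__(self) -> None:
        if min(self.mass, self.damping, self.stiffness) <= 0:
            raise ValueError("mass, damping and stiffness must be positive")
        if self.dk_max < 0:
            raise ValueError("dk_max must be >= 0")

    @property
    def resonance_hz(self) -> float:
        return np.sqrt(self.stiffness / self.mass) / (2.0 * np.pi)

    @classmethod
    def from_resonance(
        cls,
        f0_hz: float = 1000.0,
        q: float = 1.5,
        dk_max: float = 0.4,
        zs_ratio: float = 2.0,
        probe_reflectance: float = 0.5,
    ) -> "MiddleEarParams":
        """Construct from resonance frequency and quality factor."""
        m = 1.0
        k = (2.0 * np.pi * f0_hz) ** 2 * m
        r = np.sqrt(k * m) / q
        return cls(
            mass=m,
            damping=r,
            stiffness=k,
            dk_max=dk_max,
            source_impedance=zs_ratio * r,
            probe_reflectance=probe_reflectance,
        )


@dataclass(frozen=True)
class ReflexParams:
    """Static nonlinearity and dynamics of reflex activation.

    The steady-state activation is logistic in level:
    a_inf(L) = 1/(1+exp(-(L-l50)*slope)).  Activation relaxes toward
    a_inf(L(t - delay)) with time constant ``tau_attack`` when rising and
    ``tau_release`` when falling; tau_release > tau_attack yields
    hysteresis (lower offset than onset threshold).
    """

    l50: float = 99.0
    slope: float = 0.20
    delay: float = 0.15
    tau_attack: float = 0.10
    tau_release: float = 1.20

    def __post_init__(self) -> None:
        if self.tau_attack <= 0 or self.tau_release <= 0:
            raise ValueError("time constants must be positive")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")

    def a_inf(self, level_db):
        return 1.0 / (1.0 + np.exp(-(np.asarray(level_db, float) - self.l50) * self.slope))


@dataclass(frozen=True)
class NoiseParams:
    """Measurement noise model for synthetic sessions.

    ``sigma`` is the per-click, per-bin complex noise SD in units of the
    (unit) baseline relative response; ``drift_amplitude`` the SD of the
    slow real gain drift with knots every ``drift_timescale`` seconds.
    Artifacts are rare loud glitches used to exercise the weighting.
    """

    sigma: float = 0.05
    drift_amplitude: float = 0.02
    drift_timescale: float = 60.0
    artifact_probability: float = 0.0
    artifact_magnitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.drift_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.drift_timescale < 60.0:
            raise ValueError("drift timescale must be >= 60 s (removable by detrending)")


def eardrum_impedance(f, stiffness, params: MiddleEarParams):
    """Series-resonator impedance Z(f) = r + i2πf·m + k/(i2πf)."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * f_arr
    z = params.damping + 1j * omega * params.mass + stiffness / (1j * omega)
    return complex(z) if np.ndim(z) == 0 else z


def relative_pressure_change(f, activation, params: MiddleEarParams):
    """Lumped-circuit relative ear-canal pressure change R(f, a).

    Ratio of the impedance-divider pressure Z/(Z+Zs) with reflex-stiffened
    eardrum impedance to its baseline value; R(f, 0) = 1 exactly.  Below
    resonance |R| > 1 (SPL rises), above the shifted resonance |R| < 1,
    and near resonance growth in activation can be non-monotonic.
    """
    a = np.asarray(activation, dtype=float)
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("activation must lie in [0, 1]")
    zs = params.source_impedance
    k0 = params.stiffness
    za = eardrum_impedance(f, k0 * (1.0 + a * params.dk_max), params)
    z0 = eardrum_impedance(f, k0, params)
    out = (za / (za + zs)) / (z0 / (z0 + zs))
    return out


def round_trip_delay(canal_length_cm: float = 1.4, c: float = 344.0) -> float:
    """Round-trip travel time probe->eardrum->probe, s (~82 us at 1.4 cm)."""
    if canal_length_cm <= 0:
        raise ValueError("canal length must be positive")
    return 2.0 * (canal_length_cm / 100.0) / c


def reflex_activation_trajectory(
    levels_db,
    params: ReflexParams,
    click_rate: float = 20.0,
    oversample: int = 10,
) -> np.ndarray:
    """Integrate the asymmetric first-order activation dynamics.

    ``levels_db`` are the elicitor levels at the click times (sampled at
    ``click_rate``); returns activation in [0, 1] at those same times,
    starting from a(0) = 0.  Integration uses exponential-Euler substeps
    with the delayed level sampled at substep midpoints (second-order
    accurate, unconditionally stable).
    """
    levels = np.asarray(levels_db, dtype=float)
    if levels.size == 0:
        raise ValueError("levels must be non-empty")
    n = levels.size
    dt = 1.0 / click_rate
    dt_f = dt / oversample
    t_click = np.arange(n) * dt
    # delayed level at substep midpoints
    t_mid = (np.arange(n * oversample) + 0.5) * dt_f - params.delay
    l_mid = np.interp(t_mid, t_click, levels, left=levels[0], right=levels[-1])
    a_inf = params.a_inf(l_mid)
    out = np.empty(n)
    a = 0.0
    decay_a = np.exp(-dt_f / params.tau_attack)
    decay_r = np.exp(-dt_f / params.tau_release)
    for i in range(n):
        out[i] = a
        base = i * oversample
        for j in range(oversample):
            target = a_inf[base + j]
            decay = decay_a if target > a else decay_r
            a = target + (a - target) * decay
    return np.clip(out, 0.0, 1.0)


class ClickResponseModel:
    """Windowed-measurement response of the middle-ear model.

    Renders a template ear-canal click — incident pulse plus the internal
    reflection train Γe/(1−g_sΓe) with Γ the eardrum reflectance at the
    reflex-modulated stiffness — and runs the standard 1.20-ms window +
    100-Hz-bin analysis on it.  ``relative_bins(a)`` returns the per-bin
    complex response relative to baseline (a=0), interpolated from a dense
    activation grid; it is exactly 1+0i at a = 0.
    """

    def __init__(
        self,
        me: MiddleEarParams,
        fs: float = DEFAULT_FS,
        canal_length_cm: float = 1.4,
        c: float = 344.0,
        bin_centers: np.ndarray = BIN_CENTERS_HZ,
        n_fft: int = 8192,
        pulse_cutoff_hz: float = 18_000.0,
        pulse_halfwidth: int = 48,
        n_grid: int = 129,
    ) -> None:
        self.me = me
        self.fs = float(fs)
        self.bin_centers = np.asarray(bin_centers, dtype=float)
        self.n_fft = n_fft
        self.tau = round_trip_delay(canal_length_cm, c)
        if fs < 4.0 * pulse_cutoff_hz / 1.8:
            raise ValueError("sampling rate too low to represent the click")
        nn = np.arange(-pulse_halfwidth, pulse_halfwidth + 1)
        pulse = np.sinc(2.0 * pulse_cutoff_hz / fs * nn) * np.hanning(nn.size)
        self.peak_index = 4 * pulse_halfwidth
        incident = np.zeros(n_fft)
        incident[self.peak_index - pulse_halfwidth : self.peak_index + pulse_halfwidth + 1] = pulse
        self._incident = incident
        self._spec_incident = np.fft.rfft(incident)
        self._freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
        self._window = analysis_window(fs)
        # dense activation grid -> per-bin spline interpolants of D(a)/D(0)
        self._a_grid = np.linspace(0.0, 1.0, n_grid)
        d = np.array([self._bins_of(self.render_template(a)) for a in self._a_grid])
        self.baseline_bins = d[0].copy()
        rel = d / d[0]
        self._interp_re = CubicSpline(self._a_grid, rel.real, axis=0)
        self._interp_im = CubicSpline(self._a_grid, rel.imag, axis=0)

    def _reflectance(self, stiffness: float) -> np.ndarray:
        g = np.ones(self._freqs.shape, dtype=complex)
        pos = self._freqs > 0
        z = eardrum_impedance(self._freqs[pos], stiffness, self.me)
        zs = self.me.source_impedance
        g[pos] = (z - zs) / (z + zs)
        return g

    def reflected_transfer(self, activation: float) -> np.ndarray:
        """Σ_n g_s^(n-1) Γ^n e^(-i2πfnτ): the internal-reflection train."""
        k = self.me.stiffness * (1.0 + activation * self.me.dk_max)
        g = self._reflectance(k)
        e = np.exp(-2j * np.pi * self._freqs * self.tau)
        ge = g * e
        return ge / (1.0 - self.me.probe_reflectance * ge)

    def render_template(self, activation: float) -> np.ndarray:
        """Template click waveform at a given activation (peak amplitude 1)."""
        reflected = np.fft.irfft(self._spec_incident * self.reflected_transfer(activation), self.n_fft)
        return self._incident + reflected

    def _bins_of(self, waveform: np.ndarray) -> np.ndarray:
        peak = int(np.argmax(np.abs(waveform)))
        seg = waveform[peak : peak + self._window.size] * self._window
        return bin_spectra(seg, fs=self.fs, bin_centers=self.bin_centers)

    def relative_bins(self, activation) -> np.ndarray:
        """Per-bin complex response relative to baseline; shape (..., n_bins)."""
        a = np.asarray(activation, dtype=float)
        return self._interp_re(a) + 1j * self._interp_im(a)


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated session."""

    schedule: object
    middle_ear: MiddleEarParams
    reflex: ReflexParams
    noise: NoiseParams
    activation: np.ndarray  # (n_groups, n_clicks)
    drift: np.ndarray  # (n_groups, n_clicks) real gain drift
    artifact_mask: np.ndarray  # bool (n_groups, n_clicks)
    true_delay_s: float = field(default=0.0)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _drift_curve(nz: NoiseParams, t_max: float, rng: np.random.Generator):
    if nz.drift_amplitude == 0:
        return lambda t: np.zeros_like(np.asarray(t, float))
    knots = np.arange(-nz.drift_timescale, t_max + 2 * nz.drift_timescale, nz.drift_timescale)
    vals = rng.normal(0.0, nz.drift_amplitude, knots.size)
    return CubicSpline(knots, vals)


def simulate_binned_session(
    spec,
    me: MiddleEarParams | None = None,
    rf: ReflexParams | None = None,
    nz: NoiseParams | None = None,
    model: ClickResponseModel | None = None,
) -> tuple[BinnedResponseMatrix, SimulationTruth]:
    """Simulate per-click complex responses for a swept or discrete test.

    Each entry is relative_bins(a(click)) * (1 + drift(t)) + ε with ε
    complex Gaussian of SD ``nz.sigma``; a fixed seed reproduces the
    session bit-for-bit.  Swept sweeps start from zero activation (the
    analysis treats sweeps as repeats); the discrete paradigm is one
    continuous timeline, so activation elicited by one burst can linger
    into the next sequence's baseline click.
    """
    me = me or MiddleEarParams()
    rf = rf or ReflexParams()
    nz = nz or NoiseParams()
    if model is None:
        model = ClickResponseModel(me)
    if isinstance(spec, SweptScheduleSpec):
        sched = click_schedule(spec)
        n_groups, n_clicks = spec.n_sweeps, spec.clicks_per_sweep
        time_s = sched["time_s"].to_numpy().reshape(n_groups, n_clicks)
        levels = sched["elicitor_db_fpl"].to_numpy().reshape(n_groups, n_clicks)
        a_sweep = reflex_activation_trajectory(levels[0], rf, spec.click_rate)
        activation = np.tile(a_sweep, (n_groups, 1))
        paradigm = "swept"
    elif isinstance(spec, DiscreteScheduleSpec):
        sched = discrete_schedule(spec)
        n_groups, n_clicks = len(sched), 2
        time_s = sched[["click1_time_s", "click2_time_s"]].to_numpy()
        levels = np.repeat(sched[["level_db_fpl"]].to_numpy(), 2, axis=1)
        activation = _discrete_activation(sched, spec, rf)
        paradigm = "discrete"
    else:
        raise TypeError("spec must be a SweptScheduleSpec or DiscreteScheduleSpec")

    values = model.relative_bins(activation.ravel()).reshape(
        n_groups, n_clicks, len(model.bin_centers)
    )
    t_max = float(time_s.max())
    drift_fn = _drift_curve(nz, t_max, _rng(nz.seed, 1))
    drift = np.asarray(drift_fn(time_s), dtype=float).reshape(n_groups, n_clicks)
    values = values * (1.0 + drift)[..., None]
    if nz.sigma > 0:
        g = _rng(nz.seed, 2)
        noise = g.normal(0.0, nz.sigma / np.sqrt(2.0), values.shape) + 1j * g.normal(
            0.0, nz.sigma / np.sqrt(2.0), values.shape
        )
        values = values + noise
    g_art = _rng(nz.seed, 3)
    mask = g_art.random((n_groups, n_clicks)) < nz.artifact_probability
    if mask.any():
        glitch = g_art.normal(0.0, nz.artifact_magnitude / np.sqrt(2), (*values.shape,)) + 1j * g_art.normal(
            0.0, nz.artifact_magnitude / np.sqrt(2), (*values.shape,)
        )
        values = values + mask[..., None] * glitch
    matrix = BinnedResponseMatrix(
        values=values,
        bin_centers=model.bin_centers.copy(),
        time_s=time_s,
        levels_db=levels,
        paradigm=paradigm,
    )
    truth = SimulationTruth(
        schedule=spec,
        middle_ear=me,
        reflex=rf,
        noise=nz,
        activation=activation,
        drift=drift,
        artifact_mask=mask,
        true_delay_s=rf.delay,
    )
    return matrix, truth


def _discrete_activation(sched, spec: DiscreteScheduleSpec, rf: ReflexParams) -> np.ndarray:
    """Activation at both clicks of every sequence, one continuous timeline."""
    dt = 0.005
    t_end = float(sched["click2_time_s"].iloc[-1]) + 1.0
    n = int(np.ceil(t_end / dt)) + 1
    level = np.zeros(n)  # silence: nominal 0 dB FPL, negligible drive
    for _, row in sched.iterrows():
        i0 = int(round(row["burst_onset_s"] / dt))
        i1 = int(round((row["burst_onset_s"] + spec.burst_duration) / dt))
        level[i0:i1] = row["level_db_fpl"]
    shift = int(round(rf.delay / dt))
    delayed = np.concatenate([np.zeros(shift), level[: n - shift]]) if shift else level
    a_inf = rf.a_inf(delayed)
    a = np.empty(n)
    cur = 0.0
    dec_a = np.exp(-dt / rf.tau_attack)
    dec_r = np.exp(-dt / rf.tau_release)
    for i in range(n):
        a[i] = cur
        target = a_inf[i]
        dec = dec_a if target > cur else dec_r
        cur = target + (cur - target) * dec
    idx1 = np.round(sched["click1_time_s"].to_numpy() / dt).astype(int)
    idx2 = np.round(sched["click2_time_s"].to_numpy() / dt).astype(int)
    return np.stack([a[idx1], a[idx2]], axis=1)


def simulate_click_waveforms(
    truth: SimulationTruth,
    fs: float = DEFAULT_FS,
    canal_length_cm: float = 1.4,
    c: float = 344.0,
    model: ClickResponseModel | None = None,
):
    """Render the full-session probe-microphone waveform for a simulation.

    Every scheduled click becomes an incident pulse plus its internal
    reflection train at that click's true activation, scaled by the slow
    gain drift; measurement noise is added as waveform-domain white noise
    (an independent realization of the binned path's ε, matched in
    per-bin magnitude).  Returns a SessionRecording at ``fs``.
    """
    from .io import SessionRecording

    if model is None:
        model = ClickResponseModel(truth.middle_ear, fs=fs, canal_length_cm=canal_length_cm, c=c)
    spec = truth.schedule
    if isinstance(spec, SweptScheduleSpec):
        sched = click_schedule(spec)
        times = sched["time_s"].to_numpy()
        groups = sched["sweep"].to_numpy()
        clicks = sched["click_index"].to_numpy()
    else:
        sched = discrete_schedule(spec)
        times = np.column_stack(
            [sched["click1_time_s"], sched["click2_time_s"]]
        ).ravel()
        groups = np.repeat(sched["sequence_index"].to_numpy(), 2)
        clicks = np.tile([0, 1], len(sched))
    n_total = int(np.ceil((times.max() + 0.05) * fs))
    out = np.zeros(n_total)
    pre = min(150, model.peak_index)  # template samples kept before the peak
    post = 2400  # 25 ms of reflection tail, well past the analysis window
    for t, grp, clk in zip(times, groups, clicks):
        a = truth.activation[int(grp), int(clk)]
        gain = 1.0 + truth.drift[int(grp), int(clk)]
        template = model.render_template(float(a))
        seg = template[model.peak_index - pre : model.peak_index + post]
        start = int(round(t * fs)) - pre
        lo = max(start, 0)
        hi = min(start + seg.size, n_total)
        out[lo:hi] += gain * seg[lo - start : hi - start]
    nz = truth.noise
    if nz.sigma > 0:
        w = analysis_window(fs)
        scale = nz.sigma * np.abs(model.baseline_bins).mean() / np.sqrt(np.sum(w**2))
        out += _rng(nz.seed, 4).normal(0.0, scale, out.size)
    if truth.artifact_mask.any():
        g = _rng(nz.seed, 5)
        burst_len = int(0.002 * fs)
        flat = truth.artifact_mask.ravel()
        for t, bad in zip(times, flat[: times.size]):
            if bad:
                i0 = int(round(t * fs))
                out[i0 : i0 + burst_len] += g.normal(0.0, nz.artifact_magnitude, burst_len)
    return SessionRecording(samples=out.astype(np.float32), fs=float(fs))


#: priors used when drawing a population of synthetic subjects
SUBJECT_PRIORS = {
    "f0_hz": (1000.0, 75.0),
    "dk_max": (0.4, 0.08),
    "l50": (99.0, 4.0),
    "slope": (0.20, 0.025),
    "delay": (0.15, 0.04),
    "tau_attack": (0.10, 0.015),
    "tau_release": (1.20, 0.15),
}


def draw_subject_params(
    rng: np.random.Generator, priors: dict | None = None
) -> tuple[MiddleEarParams, ReflexParams]:
    """Draw one synthetic subject's middle-ear and reflex parameters.

    Gaussian priors (mean, SD) around the defaults, truncated to keep all
    parameters physical and the reflex measurable within the sweep range.
    """
    p = dict(SUBJECT_PRIORS)
    if priors:
        p.update(priors)

    def draw(name, lo, hi):
        mean, sd = p[name]
        return float(np.clip(rng.normal(mean, sd), lo, hi))

    me = MiddleEarParams.from_resonance(
        f0_hz=draw("f0_hz", 800.0, 1200.0),
        dk_max=draw("dk_max", 0.15, 0.7),
    )
    rf = ReflexParams(
        l50=draw("l50", 90.0, 106.0),
        slope=draw("slope", 0.12, 0.30),
        delay=draw("delay", 0.05, 0.30),
        tau_attack=draw("tau_attack", 0.05, 0.2),
        tau_release=draw("tau_release", 0.7, 1.8),
    )
    return me, rf
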