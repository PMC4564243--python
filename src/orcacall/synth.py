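"""Synthetic killer-whale vocalisations with known ground truth.

Real recordings from the population are not redistributable, so every
stage of the pipeline is exercised on synthetic signals that reproduce the
spectrographic structure the analysis assumes:

* whistles — frequency-modulated tones built by phase integration of a
  breakpoint contour, with optional harmonic overtones at exact integer
  multiples of the fundamental;
* burst-pulse sounds — a tonal carrier amplitude-modulated by a periodic
  pulse train, which places sidebands around the carrier at exactly the
  pulse-repetition rate; the modulation can be confined to a time window
  to emulate pulsed-middle whistles and whistle/burst-pulse transitions;
* click trains and buzzes — Gabor pulses (Gaussian-windowed cosines, the
  canonical on-axis odontocete click model) on a constant or geometrically
  ramped inter-click schedule, with optional short-delay surface/hull
  reflections;
* feature vectors — draws around the published per-group range midpoints,
  for testing the clustering stage without any audio at all.

Synthesis amplitudes are normalized; no source-level or propagation
modelling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate as _interp
from scipy import stats as _stats

from .io_formats import PARAMETER_NAMES, ReferenceGroup, WaveRecording

DEFAULT_SAMPLE_RATE = 96_000.0

#: groups whose calls carry harmonic overtones (from the published
#: per-group descriptions; BC03 explicitly had none, BC04 none reported)
HARMONIC_GROUPS = frozenset({"BC01", "BC02", "BC08", "BC09"})

#: groups whose calls are pulsed (wholly or partly)
PULSED_CLASSES = frozenset({"burst_pulse", "pulsed_middle", "transition"})


@dataclass(frozen=True)
class ContourSpec:
    """Fundamental-frequency contour as (time s, frequency kHz) breakpoints."""

    breakpoints: tuple[tuple[float, float], ...]
    interpolation: str = "cubic"  # "linear" | "cubic" (shape-preserving)

    def __post_init__(self) -> None:
        bp = tuple((float(t), float(f)) for t, f in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        times = [t for t, _ in bp]
        if len(bp) < 2:
            raise ValueError("need at least 2 breakpoints")
        if times[0] != 0.0 or any(b >= a for b, a in zip(times, times[1:])):
            raise ValueError("breakpoint times must strictly increase from 0")
        if any(f <= 0 for _, f in bp):
            raise ValueError("contour frequencies must be positive")
        if self.interpolation not in ("linear", "cubic"):
            raise ValueError("interpolation must be 'linear' or 'cubic'")

    @property
    def duration(self) -> float:
        return self.breakpoints[-1][0]

    @property
    def max_frequency(self) -> float:
        """Upper bound of the interpolated contour in kHz (shape-preserving)."""
        return max(f for _, f in self.breakpoints)

    def frequency_at(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous frequency in kHz at times ``t`` (clamped to ends)."""
        times = np.array([p[0] for p in self.breakpoints])
        freqs = np.array([p[1] for p in self.breakpoints])
        t = np.clip(np.asarray(t, dtype=float), times[0], times[-1])
        if self.interpolation == "linear" or len(times) < 3:
            return np.interp(t, times, freqs)
        # PCHIP: C1, monotone between breakpoints, no overshoot — the
        # interpolated contour stays inside the breakpoint frequency range
        return _interp.PchipInterpolator(times, freqs)(t)


@dataclass(frozen=True)
class WhistleSpec:
    contour: ContourSpec
    n_harmonics: int = 0
    harmonic_rolloff: float = 6.0  # dB per harmonic step
    snr: float | None = None  # dB; None = noiseless

    def __post_init__(self) -> None:
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")


@dataclass(frozen=True)
class BurstPulseSpec:
    contour: ContourSpec  # carrier (lowest-contour) frequency track
    pulse_rate: float  # Hz; equals the sideband spacing
    duty_cycle: float = 0.5
    snr: float | None = None
    pulsed_window: tuple[float, float] | None = None  # None = whole call

    def __post_init__(self) -> None:
        if self.pulse_rate <= 0:
            raise ValueError("pulse_rate must be positive")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty_cycle must be in (0, 1]")
        if self.pulsed_window is not None:
            a, b = self.pulsed_window
            if not (0 <= a < b <= self.contour.duration + 1e-9):
                raise ValueError("pulsed_window must lie within the call")


@dataclass(frozen=True)
class ClickTrainSpec:
    n_clicks: int
    ici: float  # s, first inter-click interval
    center_freq: float = 18.0  # kHz
    click_duration: float = 180e-6  # s, -3 dB envelope width
    polarity: int = -1  # negative Gabor by default
    ici_ramp: float = 1.0  # successive ICIs multiply by this (<1: buzz-like speed-up)
    reflection: tuple[float, float] | None = None  # (delay s, attenuation dB)
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.n_clicks < 1:
            raise ValueError("need at least one click")
        if self.ici <= 0 or self.click_duration <= 0:
            raise ValueError("ici and click_duration must be positive")
        if self.click_duration >= self.ici:
            raise ValueError("click_duration must be shorter than the ICI")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.reflection is not None and not 0 < self.reflection[0] < self.ici:
            raise ValueError("reflection delay must be positive and below the ICI")


def _phase_from_contour(
    contour: ContourSpec, sample_rate: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phase track (radians) whose derivative is the contour frequency,
    plus the sample times and the instantaneous frequency in Hz."""
    n = int(round(contour.duration * sample_rate))
    t = np.arange(n) / sample_rate
    f_hz = contour.frequency_at(t) * 1000.0
    return 2.0 * np.pi * np.cumsum(f_hz) / sample_rate, t, f_hz


def synthesize_whistle(
    spec: WhistleSpec, sample_rate: float = DEFAULT_SAMPLE_RATE, seed: int = 0
) -> WaveRecording:
    """Render a frequency-modulated tonal whistle.

    The fundamental is built by phase integration of the contour, so its
    instantaneous frequency follows the contour exactly with no segment
    discontinuities; overtone ``h`` (h = 2, 3, ...) rides at exactly
    ``h`` times the fundamental phase, ``(h-1) * harmonic_rolloff`` dB
    below the fundamental.
    """
    top = (spec.n_harmonics + 1) * spec.contour.max_frequency * 1000.0
    if sample_rate < 2.5 * top:
        raise ValueError(
            f"sample_rate {sample_rate:g} Hz too low for highest synthesized "
            f"frequency {top:g} Hz (need >= 2.5x)"
        )
    phase, _, _ = _phase_from_contour(spec.contour, sample_rate)
    x = np.sin(phase)
    for h in range(2, spec.n_harmonics + 2):
        amp = 10.0 ** (-(h - 1) * spec.harmonic_rolloff / 20.0)
        x = x + amp * np.sin(h * phase)
    x *= 0.5 / np.max(np.abs(x))
    rec = WaveRecording(samples=x, sample_rate=sample_rate)
    if spec.snr is not None:
        rec = add_noise(rec, spec.snr, seed=seed)
    return rec


def _pulse_envelope(
    t: np.ndarray, pulse_rate: float, duty_cycle: float
) -> np.ndarray:
    """Periodic unit pulse train: rectangular gates with cosine ramps.

    Period 1/pulse_rate, on-fraction = duty_cycle; at duty_cycle -> 1 the
    envelope degenerates to a constant and the sidebands vanish.
    """
    if duty_cycle >= 1.0:
        return np.ones_like(t)
    frac = (t * pulse_rate) % 1.0
    ramp = min(0.1 * duty_cycle, 0.5 * (1.0 - duty_cycle))
    env = np.zeros_like(t)
    on = frac < duty_cycle
    env[on] = 1.0
    if ramp > 0:
        rising = frac < ramp
        env[rising] = 0.5 * (1.0 - np.cos(np.pi * frac[rising] / ramp))
        fall = on & (frac > duty_cycle - ramp)
        env[fall] = 0.5 * (1.0 - np.cos(np.pi * (duty_cycle - frac[fall]) / ramp))
    return env


def synthesize_burst_pulse(
    spec: BurstPulseSpec, sample_rate: float = DEFAULT_SAMPLE_RATE, seed: int = 0
) -> WaveRecording:
    """Render a burst-pulse call as an amplitude-pulsed carrier.

    Periodic amplitude modulation at ``pulse_rate`` convolves the carrier
    line with the pulse train's Fourier series, producing the sideband
    ladder spaced by exactly the pulse-repetition rate that burst-pulse
    sounds show in spectrograms. Outside ``pulsed_window`` (when set) the
    modulation is off and the signal is a plain tonal whistle, which gives
    pulsed-middle and transition call structures.
    """
    carrier_lo = min(f for _, f in spec.contour.breakpoints) * 1000.0
    if spec.pulse_rate >= carrier_lo:
        raise ValueError(
            f"pulse_rate {spec.pulse_rate:g} Hz must be below the carrier "
            f"minimum {carrier_lo:g} Hz"
        )
    phase, t, _ = _phase_from_contour(spec.contour, sample_rate)
    x = np.sin(phase)
    env = _pulse_envelope(t, spec.pulse_rate, spec.duty_cycle)
    if spec.pulsed_window is not None:
        a, b = spec.pulsed_window
        inside = (t >= a) & (t < b)
        env = np.where(inside, env, 1.0)
    x = x * env
    x *= 0.5 / np.max(np.abs(x))
    rec = WaveRecording(samples=x, sample_rate=sample_rate)
    if spec.snr is not None:
        rec = add_noise(rec, spec.snr, seed=seed)
    return rec


def gabor_click(
    center_freq_khz: float,
    duration: float,
    sample_rate: float,
    polarity: int = -1,
) -> np.ndarray:
    """One Gabor pulse: Gaussian envelope times a cosine carrier.

    ``duration`` is the -3 dB width of the amplitude envelope. The pulse
    is truncated at +-4 sigma.
    """
    # envelope exp(-t^2 / 2 sigma^2) hits 10^(-3/20) at +- duration/2
    sigma = (duration / 2.0) / np.sqrt(2.0 * (3.0 / 20.0) * np.log(10.0))
    half = int(round(4.0 * sigma * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    return polarity * np.exp(-(t**2) / (2.0 * sigma**2)) * np.cos(
        2.0 * np.pi * center_freq_khz * 1000.0 * t
    )


def synthesize_click_train(
    spec: ClickTrainSpec, sample_rate: float = DEFAULT_SAMPLE_RATE, seed: int = 0
) -> WaveRecording:
    """Render a click train or buzz from Gabor pulses.

    Click ``i`` is placed at ``t_i = lead + sum of the first i ICIs``,
    where ICI ``j`` is ``ici * ici_ramp**j`` (constant schedule when
    ``ici_ramp == 1``). Each click may be followed by an attenuated copy
    at a fixed delay, emulating a surface or hull reflection.
    """
    icis = spec.ici * spec.ici_ramp ** np.arange(max(spec.n_clicks - 1, 0))
    click_times = np.concatenate([[0.0], np.cumsum(icis)]) + 2.0 * spec.ici
    total = click_times[-1] + 2.0 * spec.ici
    x = np.zeros(int(round(total * sample_rate)))
    pulse = gabor_click(spec.center_freq, spec.click_duration, sample_rate, spec.polarity)
    half = pulse.size // 2
    copies = [(0.0, 1.0)]
    if spec.reflection is not None:
        delay, atten_db = spec.reflection
        copies.append((delay, 10.0 ** (-abs(atten_db) / 20.0)))
    for t0 in click_times:
        for delay, gain in copies:
            i0 = int(round((t0 + delay) * sample_rate)) - half
            lo, hi = max(i0, 0), min(i0 + pulse.size, x.size)
            if hi > lo:
                x[lo:hi] += gain * pulse[lo - i0 : hi - i0]
    x *= 0.5 / np.max(np.abs(x))
    rec = WaveRecording(samples=x, sample_rate=sample_rate)
    if spec.snr is not None:
        rec = add_noise(rec, spec.snr, seed=seed)
    return rec


def add_noise(
    recording: WaveRecording,
    snr: float,
    seed: int = 0,
    band: tuple[float, float] | None = None,
) -> WaveRecording:
    """Add white Gaussian noise at a prescribed band-integrated SNR.

    SNR is defined as 10 log10 of the ratio between the signal's mean
    power and the noise power falling inside ``band`` (Hz); with
    ``band=None`` the full Nyquist band is used. For synthesized calls,
    whose energy lies entirely inside their own bandwidth, this matches
    the in-band SNR a spectrogram-based selection step would see.
    """
    if not np.isfinite(snr):
        raise ValueError("snr must be finite")
    x = recording.samples
    p_signal = float(np.mean(x**2))
    if band is None:
        band_frac = 1.0
    else:
        lo, hi = band
        band_frac = (hi - lo) / (recording.sample_rate / 2.0)
    # white noise of variance v puts v * band_frac power inside the band
    v = p_signal / (10.0 ** (snr / 10.0)) / band_frac
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(v), size=x.size)
    return WaveRecording(
        samples=x + noise,
        sample_rate=recording.sample_rate,
        start_offset=recording.start_offset,
    )


# ---------------------------------------------------------------------------
# feature-vector and whole-call surrogates built from the reference catalog


def sample_feature_vectors(
    catalog: list[ReferenceGroup],
    n_per_group: int = 20,
    spread: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw labelled synthetic feature vectors around each group's midpoints.

    Each of the nine published parameters is drawn independently from a
    Gaussian centered at the midpoint of the group's printed range with
    standard deviation ``spread`` times the range width, truncated to the
    range (so every sample lies inside its group's printed extremes).
    The published ranges are extremes over a handful of calls, so a
    midpoint-concentrated draw is more faithful than a uniform one; it
    also controls between-group overlap through ``spread``.

    Count parameters are rounded to integers. Sideband spacing for plain
    whistle groups is NaN (absent); ``has_harmonics`` and ``pulsed`` are
    group-level flags taken from the published descriptions.
    """
    if not 0 < spread <= 0.5:
        raise ValueError("spread must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    frames = []
    for group in catalog:
        cols: dict[str, np.ndarray] = {}
        for name in PARAMETER_NAMES:
            lo, hi = group.ranges[name]
            cols[name] = _truncated_normal(lo, hi, spread, n_per_group, rng)
            if name in ("n_extrema", "n_inflections"):
                cols[name] = np.clip(np.round(cols[name]), lo, hi)
        if group.sideband_range is not None:
            lo, hi = group.sideband_range
            cols["sideband_spacing"] = _truncated_normal(lo, hi, spread, n_per_group, rng)
        else:
            cols["sideband_spacing"] = np.full(n_per_group, np.nan)
        df = pd.DataFrame(cols)
        df["has_harmonics"] = group.group_id in HARMONIC_GROUPS
        df["call_class"] = group.call_class
        df["group"] = group.group_id
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _truncated_normal(
    lo: float, hi: float, spread: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    width = hi - lo
    if width <= 0:
        return np.full(n, lo)
    mid, sd = 0.5 * (lo + hi), spread * width
    a, b = (lo - mid) / sd, (hi - mid) / sd
    return _stats.truncnorm.rvs(a, b, loc=mid, scale=sd, size=n, random_state=rng)


def group_call_spec(
    group: ReferenceGroup,
    rng: np.random.Generator | None = None,
) -> WhistleSpec | BurstPulseSpec:
    """Build a synthesizable call spec representative of one catalog group.

    The contour targets the midpoint of every printed range that the
    measurement stage reads off the trace: duration, start/end frequency
    (clamped into the fundamental band), min/max frequency via alternating
    interior extrema, and the inflection count via the number of those
    extrema. Inflection targets are additionally clamped so that the
    implied FM rate (inflections / duration) stays inside the printed FM
    range. Pulsed groups get an amplitude-pulsed carrier with the pulse
    rate at the midpoint of the printed sideband spacing; the pulsed
    window covers the whole call (burst-pulse), the middle third
    (pulsed-middle) or the first half (transition).
    """
    mid = {name: 0.5 * (lo + hi) for name, (lo, hi) in group.ranges.items()}
    # small deterministic jitter (+-3%) so repeated draws of a group are
    # distinct calls while staying near the printed range midpoints
    f_scale = t_scale = 1.0
    if rng is not None:
        f_scale = float(rng.uniform(0.97, 1.03))
        t_scale = float(rng.uniform(0.97, 1.03))
    duration = mid["duration"] * t_scale
    f_lo, f_hi = mid["min_f"] * f_scale, mid["max_f"] * f_scale
    fm_lo, fm_hi = group.ranges["fm_rate"]
    n_inf = int(round(np.clip(mid["n_inflections"], fm_lo * duration, fm_hi * duration - 1.0)))
    n_inf = max(n_inf, 0)
    n_ext = n_inf + 1
    start = float(np.clip(mid["start_f"] * f_scale, f_lo, f_hi))
    end = float(np.clip(mid["end_f"] * f_scale, f_lo, f_hi))
    if n_ext == 1:
        # single-extremum (convex) contour: rise from the band floor to the
        # band ceiling and back, giving exactly one countable extremum
        start = end = f_lo
        interior = [f_hi]
    else:
        # alternate between the band extremes; begin with the extreme
        # farther from the start frequency so the first segment is large
        first_high = abs(f_hi - start) >= abs(f_lo - start)
        interior = [f_hi if (i % 2 == 0) == first_high else f_lo for i in range(n_ext)]
    times = np.linspace(0.0, duration, n_ext + 2)
    freqs = [start, *interior, end]
    contour = ContourSpec(
        breakpoints=tuple(zip(times.tolist(), freqs)), interpolation="cubic"
    )
    if group.call_class in PULSED_CLASSES and group.sideband_range is not None:
        pulse_rate = 500.0 * (group.sideband_range[0] + group.sideband_range[1])  # kHz->Hz, midpoint
        if group.call_class == "pulsed_middle":
            window = (duration / 3.0, 2.0 * duration / 3.0)
        elif group.call_class == "transition":
            window = (0.0, duration / 2.0)
        else:
            window = None
        return BurstPulseSpec(
            contour=contour, pulse_rate=pulse_rate, duty_cycle=0.5, pulsed_window=window
        )
    return WhistleSpec(
        contour=contour,
        n_harmonics=2 if group.group_id in HARMONIC_GROUPS else 0,
    )


def synthesize_group_call(
    group: ReferenceGroup,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    snr: float | None = None,
) -> WaveRecording:
    """Synthesize one representative call for a catalog group."""
    spec = group_call_spec(group)
    if snr is not None:
        spec = (
            WhistleSpec(spec.contour, spec.n_harmonics, spec.harmonic_rolloff, snr)
            if isinstance(spec, WhistleSpec)
            else BurstPulseSpec(spec.contour, spec.pulse_rate, spec.duty_cycle, snr, spec.pulsed_window)
        )
    synth = synthesize_whistle if isinstance(spec, WhistleSpec) else synthesize_burst_pulse
    return synth(spec, sample_rate=sample_rate, seed=seed)
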