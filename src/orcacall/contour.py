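"""Tonal-contour extraction and call-structure classification.

The tracker follows the lowest persistent spectral ridge — the whistle
fundamental, or the lowest visible sideband of a burst-pulse sound —
through a spectrogram, per frame:

1. candidate peaks are local maxima at least ``threshold_db`` above the
   frame's noise floor (the median spectrum level) and within
   ``dynamic_range`` dB of the spectrogram maximum;
2. candidates are linked across frames under a frequency-continuity
   constraint (``max_jump_bins`` per frame), with short dropouts bridged
   by linear interpolation;
3. among tracks at least ``min_duration`` long, the lowest-frequency one
   of the persistent tracks is returned.

Harmonic overtones are contours at integer multiples of the fundamental;
sidebands are equally spaced contours parallel to the lowest one whose
spacing equals the pulse-repetition rate. The per-frame distinction
between the two — parallel contours at integer multiples of the lowest
contour are harmonics, anything else is sidebands — drives the
whistle / burst-pulse / pulsed-middle / transition classification.
The published analysis classified calls visually; the frame-fraction
thresholds used here (20% / 80% / middle-third) are this package's own
operationalisation of those visual categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .io_formats import CallAnnotation
from .spectrogram import Spectrogram

#: recognised call-structure classes
WHISTLE = "whistle"
BURST_PULSE = "burst_pulse"
PULSED_MIDDLE = "pulsed_middle"
TRANSITION = "transition"
CALL_CLASSES = (WHISTLE, BURST_PULSE, PULSED_MIDDLE, TRANSITION)


@dataclass
class ContourTrace:
    """Ridge path: per-frame (time s, frequency kHz, level dB re max)."""

    times: np.ndarray
    freqs: np.ndarray
    levels: np.ndarray
    gaps_bridged: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if not (self.times.size == self.freqs.size == self.levels.size):
            raise ValueError("times, freqs, levels must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must strictly increase")

    @property
    def n_points(self) -> int:
        return self.times.size

    @property
    def is_empty(self) -> bool:
        return self.times.size == 0

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0


@dataclass
class OvertoneReport:
    has_harmonics: bool
    multiples_found: list[int] = field(default_factory=list)
    tolerance_used: float = 0.03


@dataclass
class SidebandReport:
    spacing: float | None  # kHz; None = absent
    n_contours_used: int = 0
    region: tuple[float, float] | None = None


def _empty_trace() -> ContourTrace:
    return ContourTrace(times=np.array([]), freqs=np.array([]), levels=np.array([]))


def _frame_candidates(
    db_frame: np.ndarray,
    threshold_db: float,
    dynamic_range: float,
    bin_slice: slice,
) -> np.ndarray:
    """Candidate ridge bins in one frame (indices into the full bin axis)."""
    floor = np.median(db_frame)
    height = max(floor + threshold_db, -dynamic_range)
    seg = db_frame[bin_slice]
    peaks, _ = _signal.find_peaks(seg, height=height)
    return peaks + (bin_slice.start or 0)


class _Track:
    __slots__ = ("frames", "bins", "levels", "gap", "bridged")

    def __init__(self, frame: int, bin_: int, level: float) -> None:
        self.frames = [frame]
        self.bins = [bin_]
        self.levels = [level]
        self.gap = 0
        self.bridged = 0


def extract_contour(
    spec: Spectrogram,
    region: CallAnnotation | None = None,
    threshold_db: float = 6.0,
    dynamic_range: float = 40.0,
    max_jump_bins: int = 3,
    max_gap_frames: int = 2,
    min_duration: float = 0.04,
) -> ContourTrace:
    """Trace the lowest persistent ridge of a spectrogram.

    ``region`` (optional) restricts the search in time and frequency, the
    way an analyst's selection box would. Returns an empty trace — not an
    exception — when no ridge at least ``min_duration`` long is found.
    The default minimum length sits just below the shortest call duration
    in the reference catalog (0.05 s).
    """
    db = spec.power_db
    frame_sel = np.arange(spec.n_frames)
    bin_slice = slice(1, None)  # never track DC
    if region is not None:
        frame_sel = np.where(
            (spec.frame_times >= region.begin_time) & (spec.frame_times <= region.end_time)
        )[0]
        lo = max(int(np.searchsorted(spec.bin_freqs, region.low_freq)), 1)
        hi = int(np.searchsorted(spec.bin_freqs, region.high_freq, side="right"))
        bin_slice = slice(lo, hi)
    open_tracks: list[_Track] = []
    done: list[_Track] = []
    for k in frame_sel:
        cands = _frame_candidates(db[k], threshold_db, dynamic_range, bin_slice)
        claimed = np.zeros(cands.size, dtype=bool)
        still_open: list[_Track] = []
        for tr in open_tracks:
            best, best_d = -1, None
            reach = max_jump_bins * (tr.gap + 1)
            for i, b in enumerate(cands):
                if claimed[i]:
                    continue
                d = abs(int(b) - tr.bins[-1])
                if d <= reach and (best_d is None or d < best_d):
                    best, best_d = i, d
            if best >= 0:
                claimed[best] = True
                if tr.gap:  # bridge the dropout by linear interpolation
                    gap_frames = np.arange(tr.frames[-1] + 1, k)
                    fb = np.interp(
                        gap_frames, [tr.frames[-1], k], [tr.bins[-1], int(cands[best])]
                    )
                    tr.frames.extend(gap_frames.tolist())
                    tr.bins.extend(fb.tolist())
                    tr.levels.extend([db[g, int(round(b))] for g, b in zip(gap_frames, fb)])
                    tr.bridged += tr.gap
                    tr.gap = 0
                tr.frames.append(int(k))
                tr.bins.append(int(cands[best]))
                tr.levels.append(float(db[k, cands[best]]))
                still_open.append(tr)
            else:
                tr.gap += 1
                (still_open if tr.gap <= max_gap_frames else done).append(tr)
        for i, b in enumerate(cands):
            if not claimed[i]:
                still_open.append(_Track(int(k), int(b), float(db[k, b])))
        open_tracks = still_open
    done.extend(open_tracks)

    def span(tr: _Track) -> float:
        return spec.frame_times[tr.frames[-1]] - spec.frame_times[tr.frames[0]]

    # track-quality gate: a real ridge stands well above the spectrogram's
    # overall median level; chance-linked chains of noise peaks do not
    noise_ceiling = float(np.median(db)) + 2.0 * threshold_db
    kept = [
        tr
        for tr in done
        if span(tr) >= min_duration
        and len(tr.frames) >= 3
        and np.median(tr.levels) >= noise_ceiling
    ]
    if not kept:
        return _empty_trace()
    longest = max(span(tr) for tr in kept)
    persistent = [tr for tr in kept if span(tr) >= 0.8 * longest]
    chosen = min(persistent, key=lambda tr: float(np.median(tr.bins)))
    freqs_khz = np.interp(chosen.bins, np.arange(spec.bin_freqs.size), spec.bin_freqs) / 1000.0
    return ContourTrace(
        times=spec.frame_times[np.asarray(chosen.frames)],
        freqs=freqs_khz,
        levels=np.asarray(chosen.levels),
        gaps_bridged=chosen.bridged,
    )


def _nearest_frames(spec: Spectrogram, times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(spec.frame_times, times)
    idx = np.clip(idx, 0, spec.n_frames - 1)
    prev = np.clip(idx - 1, 0, spec.n_frames - 1)
    use_prev = np.abs(spec.frame_times[prev] - times) < np.abs(spec.frame_times[idx] - times)
    return np.where(use_prev, prev, idx)


def detect_harmonics(
    spec: Spectrogram,
    fundamental: ContourTrace,
    tolerance: float = 0.03,
    margin_db: float = 6.0,
    dynamic_range: float = 40.0,
    max_multiple: int = 10,
) -> OvertoneReport:
    """Report which integer multiples of the fundamental carry energy.

    A multiple ``m`` counts as present in a frame when the strongest bin
    within ``tolerance`` of ``m x fundamental`` rises ``margin_db`` above
    the frame's noise floor (and within ``dynamic_range`` of the
    spectrogram maximum); it is reported when present in at least half of
    the usable frames.
    """
    if fundamental.is_empty:
        raise ValueError("fundamental trace is empty")
    db = spec.power_db
    frames = _nearest_frames(spec, fundamental.times)
    nyq = spec.bin_freqs[-1]
    found: list[int] = []
    for m in range(2, max_multiple + 1):
        target_hz = m * fundamental.freqs * 1000.0
        usable = target_hz * (1 + tolerance) < nyq
        if usable.sum() < 0.5 * fundamental.n_points:
            break
        hits = 0
        for k, f_hz in zip(frames[usable], target_hz[usable]):
            half = max(tolerance * f_hz, spec.params.bin_width)
            lo = int(np.searchsorted(spec.bin_freqs, f_hz - half))
            hi = int(np.searchsorted(spec.bin_freqs, f_hz + half, side="right"))
            if hi <= lo:
                continue
            level = db[k, lo:hi].max()
            floor = np.median(db[k])
            if level >= floor + margin_db and level >= -dynamic_range:
                hits += 1
        if hits >= 0.5 * usable.sum():
            found.append(m)
    return OvertoneReport(
        has_harmonics=bool(found), multiples_found=found, tolerance_used=tolerance
    )


def _parallel_peaks(
    spec: Spectrogram,
    db_frame: np.ndarray,
    lowest_khz: float,
    threshold_db: float,
    dynamic_range: float,
) -> np.ndarray:
    """Frequencies (kHz) of contour peaks at or above the lowest contour."""
    floor = np.median(db_frame)
    height = max(floor + threshold_db, -dynamic_range)
    peaks, _ = _signal.find_peaks(db_frame, height=height)
    f_khz = spec.bin_freqs[peaks] / 1000.0
    return f_khz[f_khz >= lowest_khz - 1.5 * spec.params.bin_width / 1000.0]


def measure_sideband_spacing(
    spec: Spectrogram,
    lowest: ContourTrace,
    region: tuple[float, float] | None = None,
    threshold_db: float = 6.0,
    dynamic_range: float = 40.0,
) -> SidebandReport:
    """Median adjacent spacing of the contours parallel to the lowest one.

    ``region`` restricts the measurement to a time window — the pulsed
    middle section, for pulsed-middle calls. Spacing is the median over
    frames of the per-frame median adjacent-peak frequency difference;
    absent when fewer than two parallel contours ever appear.
    """
    if lowest.is_empty:
        raise ValueError("lowest contour trace is empty")
    db = spec.power_db
    frames = _nearest_frames(spec, lowest.times)
    sel = np.ones(lowest.n_points, dtype=bool)
    if region is not None:
        sel = (lowest.times >= region[0]) & (lowest.times <= region[1])
    spacings: list[float] = []
    counts: list[int] = []
    for k, f0, use in zip(frames, lowest.freqs, sel):
        if not use:
            continue
        f = _parallel_peaks(spec, db[k], f0, threshold_db, dynamic_range)
        if f.size >= 3:  # lowest + at least two parallel contours
            spacings.append(float(np.median(np.diff(f))))
            counts.append(f.size)
    if not spacings:
        return SidebandReport(spacing=None, n_contours_used=0, region=region)
    return SidebandReport(
        spacing=float(np.median(spacings)),
        n_contours_used=int(np.median(counts)),
        region=region,
    )


def frame_pulsation(
    spec: Spectrogram,
    lowest: ContourTrace,
    threshold_db: float = 6.0,
    dynamic_range: float = 40.0,
    tolerance: float = 0.05,
) -> np.ndarray:
    """Per-trace-point flag: does this frame show non-harmonic sidebands?

    A frame is pulsed when at least two contours run parallel to the
    lowest one and they do not all sit at integer multiples of it (which
    would make them harmonics of a tonal sound).
    """
    if lowest.is_empty:
        raise ValueError("lowest contour trace is empty")
    db = spec.power_db
    frames = _nearest_frames(spec, lowest.times)
    pulsed = np.zeros(lowest.n_points, dtype=bool)
    for i, (k, f0) in enumerate(zip(frames, lowest.freqs)):
        f = _parallel_peaks(spec, db[k], f0, threshold_db, dynamic_range)
        others = f[np.abs(f - f0) > 1.5 * spec.params.bin_width / 1000.0]
        if others.size < 2:
            continue
        ratios = others / f0
        harmonic = np.abs(ratios - np.round(ratios)) <= tolerance * np.round(ratios)
        pulsed[i] = not np.all(harmonic)
    return pulsed


def classify_call(
    spec: Spectrogram,
    lowest: ContourTrace,
    threshold_db: float = 6.0,
    dynamic_range: float = 40.0,
) -> str:
    """Classify a call as whistle / burst-pulse / pulsed-middle / transition.

    The per-frame pulsed labels are smoothed, then: under 20% pulsed
    frames is a whistle, over 80% a burst-pulse; in between, a pulsed run
    confined to the middle of the call with tonal ends is a pulsed-middle
    whistle, and a pulsed run touching exactly one end is a transition.
    """
    pulsed = frame_pulsation(spec, lowest, threshold_db, dynamic_range)
    n = pulsed.size
    if n >= 3:  # 3-frame majority vote removes single-frame flicker
        pulsed = _signal.medfilt(pulsed.astype(int), 3).astype(bool)
    frac = pulsed.mean()
    if frac < 0.2:
        return WHISTLE
    if frac > 0.8:
        return BURST_PULSE
    runs = _runs(pulsed)
    i0, i1 = max(runs, key=lambda r: r[1] - r[0])
    starts_tonal = i0 > 0.1 * n
    ends_tonal = i1 < 0.9 * n
    if starts_tonal and ends_tonal:
        return PULSED_MIDDLE
    if starts_tonal != ends_tonal:
        return TRANSITION
    return WHISTLE if frac < 0.5 else BURST_PULSE


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs; [(0, 0)] when none."""
    if not mask.any():
        return [(0, 0)]
    edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))
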