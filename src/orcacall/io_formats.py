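"""Audio and annotation I/O, plus the packaged reference catalog.

The catalog reproduces, verbatim, the per-group measurement ranges and call
counts of the nine Bremer Canyon killer-whale call types (BC01--BC09):
four whistle groups, three burst-pulse groups, one pulsed-middle-whistle
group and one whistle/burst-pulse transition group. Frequencies are stored
in kHz, matching the published table units; annotation files keep Hz.
"""

from __future__ import annotations

import warnings
import wave as _wave
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile as _wavfile


class FormatError(ValueError):
    """Raised for unreadable or non-PCM audio files and malformed tables."""


PARAMETER_NAMES = (
    "min_f",
    "max_f",
    "start_f",
    "end_f",
    "delta_f",
    "duration",
    "n_extrema",
    "n_inflections",
    "fm_rate",
)

#: fixed column order of the measurement CSV
MEASUREMENT_COLUMNS = PARAMETER_NAMES + (
    "has_harmonics",
    "sideband_spacing",
    "call_class",
)


@dataclass
class WaveRecording:
    """Mono audio with samples normalized to [-1, 1]."""

    samples: np.ndarray
    sample_rate: float
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("recording must hold at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_offset + np.arange(self.samples.size) / self.sample_rate


@dataclass
class CallAnnotation:
    """One selection delimiting a call in time and frequency (Hz)."""

    begin_time: float
    end_time: float
    low_freq: float
    high_freq: float
    behaviour_label: str | None = None
    source_file: str | None = None

    def __post_init__(self) -> None:
        if self.end_time <= self.begin_time:
            raise ValueError("end_time must exceed begin_time")
        if not (self.high_freq > self.low_freq >= 0):
            raise ValueError("need high_freq > low_freq >= 0")


@dataclass
class ReferenceGroup:
    """Published per-group measurement ranges for one call type.

    ``ranges`` maps parameter name -> (lo, hi) in the table's units
    (kHz for frequencies, s for duration, 1/s for FM rate).
    ``sideband_range`` is None for plain whistle groups, where sideband
    spacing is undefined.
    """

    group_id: str
    call_class: str
    n_calls: int
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    sideband_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_calls < 1:
            raise ValueError("n_calls must be >= 1")
        for name, (lo, hi) in self.ranges.items():
            if hi < lo:
                raise ValueError(f"{self.group_id}: {name} range inverted")
        if self.sideband_range is not None and self.sideband_range[1] < self.sideband_range[0]:
            raise ValueError(f"{self.group_id}: sideband range inverted")


def read_wav(path: str | Path) -> WaveRecording:
    """Read a PCM WAV file, normalizing samples to [-1, 1].

    Multi-channel files are reduced to channel 0 with a warning. 16-bit and
    24-bit integer PCM (the study's two recorder formats) plus 32-bit int
    and float PCM are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy chunk warnings
            rate, data = _wavfile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - map onto a format error
        raise FormatError(f"not a readable PCM WAV file ({exc})") from exc
    if data.ndim == 2:
        warnings.warn(
            f"{path.name}: {data.shape[1]} channels, using channel 0", stacklevel=2
        )
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data / 2.0**15
    elif data.dtype == np.int32:
        # scipy left-justifies 24-bit PCM into int32
        samples = data / 2.0**31
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype.kind == "f":
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"unsupported WAV sample format {data.dtype}")
    return WaveRecording(samples=samples, sample_rate=float(rate))


def write_wav(recording: WaveRecording, path: str | Path, bit_depth: int = 24) -> None:
    """Write mono PCM WAV at 16 or 24 bit; out-of-range samples are clipped."""
    if bit_depth not in (16, 24):
        raise ValueError("bit_depth must be 16 or 24")
    if recording.samples.size == 0:
        raise ValueError("empty recording")
    x = recording.samples
    if np.any(np.abs(x) > 1.0):
        warnings.warn("samples outside [-1, 1] clipped on write", stacklevel=2)
        x = np.clip(x, -1.0, 1.0)
    full = 2 ** (bit_depth - 1)
    q = np.clip(np.round(x * full), -full, full - 1).astype(np.int32)
    if bit_depth == 16:
        _wavfile.write(str(path), int(recording.sample_rate), q.astype(np.int16))
    else:
        # stdlib wave handles the 3-byte sample packing scipy does not write
        raw = q.astype("<i4").tobytes()
        packed = b"".join(raw[i : i + 3] for i in range(0, len(raw), 4))
        with _wave.open(str(path), "wb") as fh:
            fh.setnchannels(1)
            fh.setsampwidth(3)
            fh.setframerate(int(recording.sample_rate))
            fh.writeframes(packed)


_SELECTION_COLUMNS = {
    "Begin Time (s)": "begin_time",
    "End Time (s)": "end_time",
    "Low Freq (Hz)": "low_freq",
    "High Freq (Hz)": "high_freq",
}


def read_selection_table(path: str | Path) -> list[CallAnnotation]:
    """Read a Raven-style tab-separated selection table.

    Rows violating the time/frequency invariants are dropped with a warning
    naming the row; a header-only file yields an empty list.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in _SELECTION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"selection table missing columns: {missing}")
    out: list[CallAnnotation] = []
    for i, row in table.iterrows():
        kwargs = {ours: float(row[theirs]) for theirs, ours in _SELECTION_COLUMNS.items()}
        if "Behaviour" in table.columns and isinstance(row.get("Behaviour"), str):
            kwargs["behaviour_label"] = row["Behaviour"]
        try:
            out.append(CallAnnotation(source_file=str(path), **kwargs))
        except ValueError as exc:
            warnings.warn(f"row {i + 1} rejected: {exc}", stacklevel=2)
    return out


def write_selection_table(annotations: list[CallAnnotation], path: str | Path) -> None:
    rows = [
        {
            "Begin Time (s)": a.begin_time,
            "End Time (s)": a.end_time,
            "Low Freq (Hz)": a.low_freq,
            "High Freq (Hz)": a.high_freq,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=list(_SELECTION_COLUMNS)).to_csv(path, sep="\t", index=False)


def load_reference_catalog() -> list[ReferenceGroup]:
    """Load the packaged reproduction of the published measurement tables.

    Returns the nine groups BC01--BC09 with call counts and per-parameter
    (lo, hi) ranges; whistle groups carry no sideband-spacing range.
    """
    with resources.files("orcacall.data").joinpath("reference_catalog.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    groups: list[ReferenceGroup] = []
    for _, row in table.iterrows():
        ranges = {
            name: (float(row[f"{name}_lo"]), float(row[f"{name}_hi"]))
            for name in PARAMETER_NAMES
        }
        sb = None
        if not (pd.isna(row.get("sideband_lo")) or pd.isna(row.get("sideband_hi"))):
            sb = (float(row["sideband_lo"]), float(row["sideband_hi"]))
        groups.append(
            ReferenceGroup(
                group_id=str(row["group_id"]),
                call_class=str(row["call_class"]),
                n_calls=int(row["n_calls"]),
                ranges=ranges,
                sideband_range=sb,
            )
        )
    return groups


def write_measurement_table(measurements, path: str | Path) -> None:
    """Write call measurements as CSV in the documented fixed column order.

    Sideband spacing that is absent (whistles) is written as an empty cell,
    never as 0 -- a 0 kHz pulse-repetition spacing is physically meaningless.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("no measurements to write")
    rows = []
    for m in measurements:
        row = {name: getattr(m, name) for name in PARAMETER_NAMES}
        row["has_harmonics"] = bool(m.has_harmonics)
        row["sideband_spacing"] = (
            "" if m.sideband_spacing is None else m.sideband_spacing
        )
        row["call_class"] = m.call_class
        rows.append(row)
    pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS)).to_csv(path, index=False)


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV back; empty sideband cells become NaN (absent)."""
    table = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"measurement table missing columns: {missing}")
    return table


def measurements_from_table(table: pd.DataFrame) -> list:
    """Rebuild CallMeasurement objects from a measurement table."""
    from .features import CallMeasurement

    out = []
    for _, row in table.iterrows():
        sb = row["sideband_spacing"]
        out.append(
            CallMeasurement(
                **{name: row[name] for name in PARAMETER_NAMES},
                has_harmonics=bool(row["has_harmonics"]),
                sideband_spacing=None if pd.isna(sb) else float(sb),
                call_class=str(row["call_class"]),
            )
        )
    return out
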