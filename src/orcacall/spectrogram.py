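"""Short-time Fourier power spectrograms.

All spectrograms use a Hamming window with 50% overlap by default — the
parameterization under which the call-type catalog was measured. Power is
kept linear internally (needed for SNR arithmetic); a dB-re-max view is
provided for display and thresholding, since the recordings carry no
absolute calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .io_formats import WaveRecording


@dataclass(frozen=True)
class SpectrogramParams:
    nfft: int = 512
    overlap: float = 0.5
    sample_rate: float = 96_000.0
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.nfft <= 0 or self.nfft % 2:
            raise ValueError("nfft must be a positive even integer")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    @property
    def hop(self) -> int:
        return int(round(self.nfft * (1.0 - self.overlap)))

    @property
    def bin_width(self) -> float:
        """Frequency resolution in Hz."""
        return self.sample_rate / self.nfft

    @property
    def frame_step(self) -> float:
        """Time between successive frame centers in seconds."""
        return self.hop / self.sample_rate


@dataclass
class Spectrogram:
    """One-sided power spectrogram: ``power[frame, bin]`` (linear units)."""

    power: np.ndarray
    frame_times: np.ndarray
    bin_freqs: np.ndarray
    params: SpectrogramParams

    @property
    def power_db(self) -> np.ndarray:
        """Power in dB relative to the spectrogram maximum."""
        ref = self.power.max()
        if ref <= 0:
            return np.full_like(self.power, -np.inf)
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.power / ref)

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]


def compute_spectrogram(
    recording: WaveRecording, params: SpectrogramParams | None = None
) -> Spectrogram:
    """STFT power spectrogram of a mono recording.

    Frame ``k`` covers samples ``[k*hop, k*hop + nfft)`` with no padding and
    no detrending; its time stamp is the center of that span plus the
    recording's start offset.
    """
    if params is None:
        params = SpectrogramParams(sample_rate=recording.sample_rate)
    if params.sample_rate != recording.sample_rate:
        params = SpectrogramParams(
            nfft=params.nfft, overlap=params.overlap,
            sample_rate=recording.sample_rate, window=params.window,
        )
    if recording.samples.size < params.nfft:
        raise ValueError(
            f"recording ({recording.samples.size} samples) shorter than nfft ({params.nfft})"
        )
    freqs, times, sxx = _signal.spectrogram(
        recording.samples,
        fs=recording.sample_rate,
        window=params.window,
        nperseg=params.nfft,
        noverlap=params.nfft - params.hop,
        detrend=False,
        scaling="spectrum",
        mode="psd",
    )
    return Spectrogram(
        power=sxx.T.astype(np.float64),
        frame_times=times + recording.start_offset,
        bin_freqs=freqs,
        params=params,
    )
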