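import numpy as np
import pytest

import orcacall as oc


@pytest.fixture(scope="session")
def catalog():
    return oc.load_reference_catalog()


@pytest.fixture(scope="session")
def upsweep_spec():
    """BC01-style upsweep: 5 -> 8 kHz over 1.2 s."""
    return oc.WhistleSpec(
        contour=oc.ContourSpec(breakpoints=((0.0, 5.0), (1.2, 8.0)), interpolation="linear")
    )


@pytest.fixture(scope="session")
def upsweep_recording(upsweep_spec):
    return oc.synthesize_whistle(upsweep_spec)


@pytest.fixture(scope="session")
def upsweep_spectrogram(upsweep_recording):
    return oc.compute_spectrogram(upsweep_recording)


@pytest.fixture(scope="session")
def pulsed_carrier():
    """4 kHz constant carrier pulsed at 500 Hz for 1 s."""
    spec = oc.BurstPulseSpec(
        contour=oc.ContourSpec(((0.0, 4.0), (1.0, 4.0)), "linear"), pulse_rate=500.0
    )
    rec = oc.synthesize_burst_pulse(spec)
    return spec, rec, oc.compute_spectrogram(rec)


@pytest.fixture()
def dense_sine_trace():
    """Analytic contour f(t) = 8 + 2 sin(2 pi t) kHz over 3 s.

    Stationary points at t = 0.25, 0.75, ..., 2.75 (six) and curvature
    zero crossings at t = 0.5, 1.0, ..., 2.5 (five).
    """
    t = np.arange(0.0, 3.0, 0.01)
    f = 8.0 + 2.0 * np.sin(2.0 * np.pi * t)
    return oc.ContourTrace(times=t, freqs=f, levels=np.zeros_like(t))
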