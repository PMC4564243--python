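# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal models (synthesis)

**Whistles.** A whistle is a frequency-modulated tone defined by a
breakpoint contour (time s, frequency kHz). The waveform is built by
phase integration — φ(t) = 2π ∫ f(τ) dτ, sampled as a cumulative sum —
so the instantaneous frequency follows the contour exactly and there are
no phase discontinuities at breakpoints. Contours are interpolated
linearly or with a shape-preserving cubic (PCHIP); PCHIP is the default
because it cannot overshoot the breakpoint frequencies, which keeps the
synthesized extremes equal to the intended ones. Overtone *h*
(h = 2, 3, …) rides at exactly *h*× the fundamental phase, attenuated by
(h−1) × `harmonic_rolloff` dB (default 6 dB per step). Synthesis refuses
configurations whose highest component exceeds sample_rate / 2.5.

**Burst-pulse sounds** are rendered as an amplitude-pulsed carrier: the
carrier follows a contour exactly as a whistle does, and is multiplied by
a periodic gate at `pulse_rate` Hz (rectangular with 10%-of-duty cosine
ramps, on-fraction `duty_cycle`, default 0.5). Periodic amplitude
modulation convolves the carrier line with the gate's Fourier series,
which is precisely the spectrographic signature of a burst-pulse sound:
a ladder of sidebands spaced by the pulse-repetition rate. At
`duty_cycle → 1` the gate degenerates to a constant and the sidebands
vanish. Restricting the gate to a time window produces pulsed-middle
calls (window in the call's middle) and whistle/burst-pulse transitions
(window covering one half).

**Clicks** are Gabor pulses — Gaussian-enveloped cosines, the canonical
model of an on-axis odontocete click — with duration defined as the
−3 dB width of the amplitude envelope (default 180 µs, center frequency
18 kHz, negative polarity). Trains place clicks on a constant or
geometrically ramped inter-click schedule; an optional reflection adds
an attenuated copy of each click at a fixed delay, emulating a surface
or hull echo.

**Noise.** `add_noise` adds white Gaussian noise calibrated so that
10·log₁₀(signal power / noise power inside a chosen band) equals the
requested SNR; with no band given the full Nyquist band is used. For the
synthetic calls, whose energy lies inside their own bandwidth, this
matches the in-band SNR a spectrogram-based screening step would see.
Synthesis amplitudes are normalized; no source levels, propagation loss
or Doppler are modelled, so any level-dependent behaviour of real
recordings is untested by design.

**Feature-vector sampling.** For clustering experiments without audio,
`sample_feature_vectors` draws each parameter independently from a
Gaussian centered at the midpoint of the group's published range with
σ = `spread` × range width, truncated to the range (default spread
0.05). The published ranges are extremes over a handful of calls, so a
midpoint-concentrated draw is more faithful than a uniform one, which
would overlap neighbouring groups heavily. Count parameters are rounded;
sideband spacing is absent (NaN) for whistle groups; harmonic and
pulsed flags are group-level constants taken from the published group
descriptions (overtones present in BC01, BC02, BC08, BC09; absent in
BC03; not reported for BC04 and the plain burst-pulse groups, encoded
as absent).

**Whole-call surrogates.** `group_call_spec` builds one synthesizable
call per catalog group: duration and band at the printed midpoints,
alternating interior extrema to hit the printed min/max, the inflection
target clamped so that inflections/duration stays inside the printed FM
range, and — for pulsed groups — pulse rate at the sideband-spacing
midpoint with the gate over the whole call, the middle third, or the
first half according to the group's class. An optional ±3% deterministic
jitter makes repeated draws distinct calls.

## Spectrograms

Hamming window, 50% overlap, NFFT 512 at 96 kHz by default (frequency
bin 187.5 Hz, hop 256 samples ≈ 2.67 ms) — the parameterization under
which the reference catalog was measured. Frame *k* covers samples
[k·hop, k·hop + nfft) with no zero-padding and no detrending; its time
stamp is the center of that span, so a call's measured duration equals
the first-to-last frame-center difference. Power is kept linear
internally (the Parseval identity against windowed segment energy is
tested); display and thresholding use dB relative to the spectrogram
maximum, since the recordings carry no absolute calibration.

## Contour extraction

Ridge tracking, per frame: candidate peaks must rise ≥ `threshold_db`
(default 6 dB, a conventional good-SNR margin) above the frame's noise
floor — its median spectrum level — and lie within `dynamic_range`
(default 40 dB) of the spectrogram maximum. Candidates are linked across
frames under a continuity constraint of ≤ 3 bins per frame (whistle
contours are continuous by definition); dropouts of up to 2 frames are
bridged by linear interpolation and counted. Tracks shorter than
`min_duration` (default 0.04 s, just below the shortest printed call
duration of 0.05 s) are discarded, as are tracks whose median level is
below the global median + 2×`threshold_db` — chance-linked chains of
noise peaks fail this gate, so pure noise yields an empty trace rather
than an exception. Among surviving tracks, those spanning at least 80%
of the longest are "persistent", and the lowest-frequency persistent
track is returned: the whistle fundamental, or the lowest visible
sideband of a pulsed call. An analyst-style selection box (time ×
frequency) can restrict the search.

**Harmonics vs sidebands.** Overtone detection walks integer multiples
of the traced fundamental and reports multiple *m* when the strongest
bin within ±3% of m·f (bin-quantization tolerance) clears the frame
noise floor by 6 dB in at least half the usable frames. Sideband spacing
is the median over frames of the per-frame median adjacent-peak
difference among contours parallel to the lowest one, absent when fewer
than two parallel contours ever appear; the estimate is amplitude-scale
invariant, and a region argument restricts it to the pulsed section for
pulsed-middle calls. The per-frame pulsed/tonal distinction is:
parallel contours present that are *not all at integer multiples* of the
lowest contour. (An "is the spacing an integer divisor of the lowest
frequency" rule fails whenever the lowest visible sideband happens to
be an exact multiple of the spacing — e.g. a 4 kHz carrier pulsed at
500 Hz with its lowest visible sideband at 2.5 kHz — whereas the
all-integer-multiples test is exactly the harmonic-pattern criterion.)

**Call classes.** The published analysis classified call structure
visually; the frame-fraction thresholds here are this package's own
operationalisation and are, by construction, not comparable call-by-call
with a human analyst: after a 3-frame majority vote on the pulsed
labels, < 20% pulsed frames → whistle, > 80% → burst-pulse; otherwise a
pulsed run with tonal material on both sides (> 10% of frames each) →
pulsed-middle whistle, a pulsed run touching exactly one end →
transition.

## Call-parameter measurement

Raw traces are quantized to the frequency-bin grid, so the contour is
median-filtered then moving-averaged (both 5 frames, windows shrinking
symmetrically at the endpoints) before anything is counted. Frequency
parameters and duration are read off the smoothed trace. For
pulsed-middle and transition calls, the frequency parameters are
measured off the tonal (whistle-fundamental) portion while duration and
the modulation counts cover the entire call, following the catalog's
footnoted convention for those groups. One consequence is accepted
deliberately: this package keeps min f ≤ start f, end f ≤ max f for
every call, whereas the published BC08 row has start frequencies above
its maximum frequency because start was read off a different part of the
call than min/max. Where the lowest sideband of a pulsed call becomes
visible also depends on level and band selection, so start/end
frequencies of pulsed calls are only loosely comparable with the printed
ranges (the test suite checks all parameters against the printed ranges
for whistle groups, and excludes start/end for pulsed groups).

**Extrema** are interior sign changes of the first difference gated by a
prominence threshold of 2 frequency bins (default): only excursions that
are real at the spectrogram's own resolution count, and endpoints are
never stationary points. **Inflections** are interior extrema of the
(mean-smoothed) slope sequence gated at 1 bin — the ridge quantization
step, hence the magnitude of spurious slope structure — and the count is
floored at n_extrema − 1: between two consecutive counted stationary
points a smooth contour must change curvature at least once, so the
floor only restores gate-suppressed true inflections. This floor is also
what guarantees the invariant n_inflections ≥ n_extrema − 1, which the
published per-group count ranges are consistent with. The identities
Δf = Max f − Min f and FM rate = inflections / duration hold exactly on
every output. The published counts come from an unstated convention, so
only range-level agreement with the catalog is claimable, never per-call
equality.

## Click detection

Band-pass (Butterworth order 4, default 5–40 kHz, bracketing the
12–24 kHz band where killer-whale click energy peaks), envelope by
rectification + 8 kHz low-pass, threshold = envelope median + 10×MAD
with a floor at 5% of the envelope peak (the relative floor makes
detection invariant to amplitude scaling, and matters in noiseless
synthesis where the MAD is near zero), and a refractory period of 1 ms.
The refractory default sits between the reflection delays (~0.4–0.5 ms)
and the shortest buzz inter-click intervals (~2–2.5 ms) reported for
this population — buzz clicks separate while each click's reflection
folds into its parent event. The published text and figure captions
disagree on the exact buzz values (ICI 2.5 vs 2 ms; reflections 0.5 vs
0.4 ms; peak energy 12–24 vs 12–23 kHz); the body-text values are used
as canonical defaults and targets, without judging which measurement is
correct. Click duration is the −3 dB width of the analytic (Hilbert)
envelope around each peak; peak frequency is the spectral argmax of a
short Hann-windowed snippet; a secondary envelope peak 0.15–1 ms after a
click, at ≥ 3% of the click's own height (≈ −30 dB attribution margin),
is recorded as its reflection, and the reflection delay is reported when
at least half the clicks show one.

## Clustering

Features: the nine measured parameters plus the harmonic flag (0/1),
sideband spacing (0 where absent) and a pulsed-class indicator —
twelve columns, z-scored; constant columns are dropped with a warning.
Standardization is a deliberate choice the original analysis does not
state: without it the kHz-scale parameters would dominate the counts.

The k-means core is implemented in-package so its semantics are fully
specified: k-means++ seeding, Lloyd iterations, ties in nearest-centroid
assignment broken toward the lowest centroid index, empty clusters
repaired by reassigning the point farthest from its centroid,
best-of-restarts by within-cluster sum of squares (monotonicity over
iterations is asserted at run time). Rows are put into a canonical
lexicographic order before any seeded draw, so results are invariant to
input row order; a single integer seed drives everything. scikit-learn's
KMeans is used in the test suite as an independent cross-check, never as
the engine. Lloyd's algorithm is a local optimizer: agreement with the
exhaustive-bipartition optimum on small instances is a property of
best-of-enough-restarts (the tests use 50), not of a single run.

Both clustering modes are provided, because the original workflow's mode
is unstated: fixed k (default 9, the published repertoire size) and
silhouette selection over a k range (ties toward smaller k). Whether
sideband spacing and the harmonic flag entered the original feature
vectors is also unstated; including them (with absent → 0) is this
package's choice.

## Pipeline and problem sizes

The default pipeline synthesizes 5 calls per catalog group (45 calls) at
30 dB SNR with ±3% jitter, measures them, and clusters at k = 9 — a
deliberately compact configuration that exercises every stage in a few
seconds while giving every group enough members to form a cluster. The
acceptance script samples 20 feature vectors per group (180 rows) for
the cluster-count check, the size at which the spec'd recovery
properties are defined, and uses a 50-click buzz for the ICI check. The
run manifest accounts for every call (detected = measured + excluded),
mirroring the structure of a field-data screening funnel, not its
numbers.

## What passing tests do and do not show

The synthetic calls are clean single sources: no overlapping callers, no
propagation distortion, no vessel noise, no Doppler, and contours drawn
from idealized breakpoint shapes. Passing recovery tests therefore
demonstrates that the measurement chain is internally consistent and
unbiased at spectrogram resolution under the stated noise model — not
that it reproduces a human analyst's tracings of field recordings.
Per-call equality with the published measurements is unattainable in
principle (the recordings are not deposited and the tracing convention
is unstated); the claimable and tested statement is range-level
consistency: surrogate calls built inside a group's printed ranges
measure back inside those ranges at spectrogram resolution, and feature
vectors sampled around the printed midpoints cluster back into nine
groups. Multi-animal overlapping calls are out of scope — extraction
follows the single lowest persistent ridge in the annotated region.
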