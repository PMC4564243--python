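# orcacall

Analysis of killer whale (*Orcinus orca*) vocalisations: synthesis of
whistles, burst-pulse sounds and echolocation click trains; spectrogram
computation; tonal-contour extraction; measurement of the standard call
parameters; and k-means categorisation of calls into call types.

## The problem

Killer whale populations differ in their acoustic repertoires, and a
quantitative description of a repertoire — the recurring "call types" a
population produces — is the foundation for passive acoustic monitoring
and for comparisons between populations. The workflow this package
implements is the standard one for odontocete call categorisation:

1. **Spectrograms** of field recordings (Hamming window, 50% overlap,
   NFFT 512 at 96 kHz by default).
2. **Contour extraction**: trace the fundamental of each whistle, or the
   lowest contour of each burst-pulse sound, as a time–frequency ridge.
3. **Call parameters** per call, measured off the contour:
   minimum frequency (Min f), maximum frequency (Max f), frequency range
   (Δf = Max f − Min f), start and end frequency, duration, number of
   extrema (stationary points of the contour), number of inflection
   points (curvature sign changes), FM rate = inflections / duration,
   presence of harmonic overtones, and — for pulsed calls — the sideband
   spacing, which equals the pulse-repetition rate.
4. **Categorisation**: each call's parameters form a feature vector;
   k-means clustering (Lloyd iterations with k-means++ seeding,
   minimising the within-cluster sum of squared Euclidean distances on
   z-scored features) groups the calls into call types, either at a
   fixed k or with k selected by silhouette.
5. **Click trains**: clicks are modelled as Gabor pulses (Gaussian-
   windowed cosines); the detector measures inter-click intervals, click
   duration, spectral peak, and short-delay reflections.

Field recordings of the population this workflow was built around are
not redistributable, so the package ships (a) a machine-readable
reproduction of the published nine-group measurement tables (call types
BC01–BC09, 142 calls: per-group parameter ranges and counts), and (b) a
synthesis module that generates whistles, burst-pulse sounds,
pulsed-middle and transition calls, and click trains with known ground
truth, at controllable SNR. Every stage is validated by parameter
recovery on those synthetic signals.

## Worked example

Synthesize an upsweeping whistle (5 → 8 kHz over 1.2 s, two harmonic
overtones — the shape of a BC01-type call) and measure it:

```sh
$ echo '{"contour": {"breakpoints": [[0.0, 5.0], [1.2, 8.0]]}, "n_harmonics": 2}' > call.json
$ orcacall synth whistle --spec call.json --out call.wav
call.wav: 115200 samples at 96000 Hz
$ orcacall measure call.wav --out call_features.csv
1 calls measured -> call_features.csv
$ cat call_features.csv
min_f,max_f,start_f,end_f,delta_f,duration,n_extrema,n_inflections,fm_rate,has_harmonics,sideband_spacing,call_class
5.0625,8.0625,5.0625,8.0625,3.0,1.1946666666666668,0,0,0.0,True,,whistle
```

The start/end frequencies come back within one spectrogram bin
(187.5 Hz) of the synthesized 5 and 8 kHz; the monotone sweep has no
extrema or inflections, hence FM rate 0; the harmonic flag is set; the
sideband-spacing cell is empty because the call is tonal, not pulsed.

The full pipeline — synthesize a repertoire from the packaged catalog
(5 calls per group at 30 dB SNR), measure every call, cluster at k = 9,
and write the range tables:

```sh
$ orcacall pipeline --out run
...
"calls_in": 45, "calls_measured": 45, "calls_excluded": 0, "k": 9, "n_groups": 9
```

`run/features.csv` holds the 45 measured feature vectors,
`run/assignments.csv` the cluster memberships, and `run/groups.csv` the
per-group parameter ranges in the shape of the published tables. The same
config and seed reproduce all three files byte-identically.

The same stages are available as library functions
(`orcacall.synthesize_whistle`, `extract_contour`, `measure_call`,
`kmeans`, `detect_clicks`, ...); see the module docstrings.

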