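# Methods

## Signal model

A droplet-generation clip is an ordered stack of m × n grayscale frames
captured at a constant, caller-supplied frame rate fs. Frame i is unrolled
column-major (column 1 top-to-bottom, then column 2, …) into a grayscale
vector **h**(i); the similarity signal is

    s(i) = h(i)ᵀ h(r) / (‖h(i)‖ ‖h(r)‖),   i = 0 … N−1,

with reference frame r (default: the first frame of the clip or window).
For non-negative intensities s(i) ∈ [0, 1], s(r) = 1, and s is invariant to
any positive rescaling of the pixel values and to any fixed pixel
permutation applied to all frames — which is why bit depth, normalisation
constants and the particular flattening order never affect results. If
droplets are generated at frequency f, the image content recurs with period
1/f and s is periodic at f (plus harmonics: the waveform is periodic but
far from sinusoidal, since a droplet crossing the field produces sharp
similarity dips).

Assumptions: constant frame rate; a fixed camera and static background;
fs > 2f (Nyquist), in practice fs ≥ 5f as an acquisition rule — estimates
whose fundamental exceeds 0.4·fs raise an aliasing warning.

## Spectrum and estimator

The similarity vector is mean-subtracted (the offset near 1 carries no
frequency information; the DC bin is zeroed), multiplied by a periodic Hann
window, and transformed with an FFT. The one-sided power spectrum is
normalised so that, for a rectangular window, total power equals N·var(s)
(Parseval). Grid spacing is Δf = fs/N.

**Peak selection.** Candidate peaks are local maxima whose power is at least
`prominence_frac` of the global maximum (default 0.5 single-channel) *and*
at least 25× the median spectral power. The median-floor criterion is what
rejects a pure-noise spectrum — a relative-to-maximum rule alone cannot,
because the global maximum always qualifies against itself; white-noise
periodogram maxima stay below ~17× the median for clips up to several
thousand frames, so 25× separates the two regimes with margin. The
fundamental is the *lowest-frequency* qualifying peak, not the global
maximum: harmonics of the droplet rate are often stronger than the
fundamental itself. Equal-power ties resolve to the lower frequency.

**Mean frequency.** f̄ is the power-weighted centroid of the narrow band
around the fundamental peak: the contiguous FWHM bins widened to at least
the peak's two immediate neighbours, capped at ±5% of the peak frequency.
With a Hann taper the spectral line of a stable tone spans ~3 bins whatever
its offset δ from the grid, and the 3-bin power centroid locates it with a
worst-case bias of ~0.03 bin (at |δ| ≈ 0.5); a rectangular window was
rejected as the default because it concentrates the line into a single bin
at small δ, leaving any centroid with a worst-case bias of ~0.2–0.5 bin —
i.e. no better than peak-picking. Rectangular remains available by flag.

**CV.** CV_f = 100 · σ/μ, where μ and σ are the power-weighted mean and
standard deviation of frequency over the *fundamental region*: every bin
within ±5% of the peak frequency. The wider support (compared with the FWHM
band) is deliberate: when the generation rate wanders or steps during a
clip, the line smears or splits inside the region and σ inflates, while a
FWHM-hugging width would stay blind to a split line. For a stable process
CV_f degenerates to the window-limited width, ~0.8·Δf/f̄ — so CV floors
scale like 1/N and stable-versus-disturbed comparisons should use equal
window lengths. CV_f is a spectral-width statistic; it tracks, but does not
equal, the CV of inter-droplet intervals.

**Multi-channel detection.** Every qualifying local maximum (default
`prominence_frac` 0.05 — composite channels at different magnification span
an order of magnitude in peak power) is scanned in ascending frequency; a
peak within 2% of an integer multiple (2×–6×) of an already-accepted
stronger lower peak is grouped as its harmonic. Surviving fundamentals get
disjoint bands (overlaps truncated at midpoints) and independent estimates.
Reported fundamentals are therefore never near-multiples of each other.

## Streaming

The real-time mode keeps two index-aligned FIFO buffers of capacity
N (default 5,000): frames and their similarities against a reference fixed
at stream initialisation. Build-up phase (buffer filling) estimates are
flagged provisional with Δf = fs/(frames so far); once full, each admitted
frame evicts the oldest pair. Per push the only similarity work is one dot
product of length R = m·n against the cached unit reference — asserted in
tests by operation count, not wall clock, since timing is
hardware-dependent. The spectrum is recomputed by full FFT on demand (at
N = 5,000 this is negligible next to the dot product); no sliding-DFT
incrementalism is attempted. Batch and streaming paths share one similarity
routine and are bit-identical on the same frames. An optional re-reference
hook recomputes the buffer against a new reference when the fundamental's
power collapses after a regime change (default off).

The windowed monitor cuts a stream into windows of fixed length (default
non-overlapping) and runs the batch pipeline per window with that window's
first frame as reference, so a regime change cannot strand later windows on
a stale reference.

## Synthetic videos

The simulator renders what the camera sees: a bright channel band with dark
walls crossing a 62 × 512 field (defaults), dark anti-aliased circular
droplets (diameter 20 px) born at an off-screen nozzle at the scheduled
instantaneous rate and advected at speed = spacing × frequency
(spacing 40 px centre-to-centre), optional inter-droplet interval jitter,
and Gaussian pixel noise (σ = 2 on a ~120-contrast scale) clipped at zero.
Everything is deterministic given the seed. Anti-aliased disks matter:
hard-edged disks make s(i) piecewise-constant in time and alias the
spectrum. Jitter-free constant-frequency clips are exactly periodic by
construction (births are computed by direct indexing, not interval
accumulation).

Disturbances are modelled as piecewise-constant frequency schedules, not
fluid dynamics. The simulator reproduces the periodic-reappearance
structure the method measures and nothing else: no break-up-regime
morphology, no droplet deformation, no illumination drift, no motion blur,
no camera vignetting. Passing tests therefore demonstrate correct recovery
of periodic image recurrence under noise and geometric transformation —
not robustness to every artefact of real footage.

Multi-channel composites transform each source clip (zoom, then rotation,
bilinear, zero fill) and paint it onto a square canvas at its anchor, later
channels over earlier ones, emulating video-editor layering; vertical
stacking covers the parallel-channel case. Channel geometry is static, so
each channel's support mask is computed once.

## Validation scale and numerical choices

The test suite and the acceptance script validate at the canonical camera
geometry: 5,000-frame clips at 62 × 512 for the frequency sweep
{67.3, 90.1, 410.4, 1200.0, 1584.3, 1921.0, 3563.1, 4707.9} Hz with frame
rates 5–8× each frequency; 1,000-frame clips for the single-channel and
composite comparisons (composites re-simulated at a common 10,000 fps
rather than resampling rendered video, avoiding interpolation artefacts);
512 × 512 three-channel canvases with zooms 110/200/150% and rotations
−13°/3°/147°. Unit tests use a reduced 32 × 128 geometry for speed; the
physics is scale-free.

Numerical choices: similarities in float64 via a single normalised
reference; frames stored float32; FFT via numpy rfft; degenerate (constant)
similarity vectors are flagged rather than estimated; all-zero frames abort
with the frame index (a black frame signals acquisition failure, and
skipping would corrupt the time base); lossless persistence uses TIFF
(float-exact), with AVI delegated to imageio when an ffmpeg backend exists.
Reports use seconds, never frame indices; CSV columns are fixed
(`window_start_s, window_end_s, mean_freq_hz, cv_percent, peak_power,
n_frames`), and JSON reports embed the resolved run configuration.

## Known limitations

- The CV is a spectral width over a ±5% region: frequency excursions beyond
  ±5% of the fundamental (e.g. a hard doubling of the rate inside one
  window) register as a second peak, not as width, and are better detected
  by per-window mean tracking or the multi-channel detector.
- Channels in a composite whose rates are within ~2% of an integer ratio of
  a stronger channel are grouped as harmonics and missed.
- Very weak channels (fundamental below 5% of the strongest channel's peak,
  or below the 25× noise floor) are not detected without lowering the
  thresholds.
- Frame rate is trusted as given; a wrong frame rate rescales all reported
  frequencies proportionally.
- Wall-clock performance is hardware-dependent and deliberately untested;
  the per-push cost contract is stated in operation counts.
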