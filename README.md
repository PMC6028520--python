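# dropfreq

Fast, accurate monitoring of droplet-generation processes in droplet
microfluidics from high-speed microscopy video.

Droplet microfluidic devices emit monodisperse emulsion droplets at rates
from tens of Hz to several kHz. The generation frequency and its stability
(coefficient of variation, CV) are sensitive online indicators of process
health — flow interruptions, pump glitches and clogging all perturb them —
but per-droplet image analysis is too slow to keep up, and manual
counting-timing is laborious and coarse.

`dropfreq` measures the frequency without segmenting a single droplet. Each
grayscale frame of an m × n clip is unrolled column-major into a vector
**h**(i), and every frame is compared with a fixed reference frame r through
the cosine similarity

    S(h(i), h(r)) = h(i)ᵀ h(r) / (‖h(i)‖ ‖h(r)‖)

A stable generation process is periodic, so the reference configuration
recurs and the similarity time series oscillates at the droplet-generation
frequency. The one-sided power spectrum of the detrended, Hann-tapered
similarity vector (the *cyclic auto-spectrum*) concentrates this oscillation
into a sharp fundamental line: the reported mean frequency f̄ is the
power-weighted centroid of the bins around that line, and CV_f is the
power-weighted spectral width of the surrounding fundamental region divided
by its centroid. Because each new frame costs exactly one dot product
against the cached reference vector, the same machinery runs in batch,
windowed-monitoring, and FIFO-buffered real-time modes. Composite clips with
several channels yield one fundamental per channel in a single run, with
harmonics grouped automatically.

A bundled synthetic-video simulator (moving anti-aliased droplets with a
configurable frequency schedule, jitter and pixel noise) provides ground
truth for every mode.

## Worked example

Simulate a 250 Hz process filmed at 2,000 fps for 500 frames, then estimate:

```sh
$ dropfreq simulate --frequency 250 --frame-rate 2000 --n-frames 500 \
      --seed 17 --out sim.tif
$ dropfreq estimate --input sim.tif --frame-rate 2000 --output est.csv
$ cat est.csv
window_start_s,window_end_s,mean_freq_hz,cv_percent,peak_power,n_frames
0,0.25,249.8822293,0.9220183544,0.02111870305,500
```

The clip covers 0–0.25 s; the estimated mean generation frequency is
249.88 Hz — the generating value recovered well within the 4 Hz spectral
bin of a 500-frame clip — with a frequency CV of 0.92%, the narrow spectral
width of a stable process at this short clip length. `peak_power` is the spectral
power in the fundamental bin and is mainly useful for tracking signal
quality over time. The same library calls are available in Python:

```python
from dropfreq import SyntheticVideoConfig, generate_video, estimate_clip

stack, truth = generate_video(
    SyntheticVideoConfig.stable(250.0, 2000.0, 500, seed=17))
est = estimate_clip(stack)           # reference frame = frame 0
print(est.mean_freq_hz, est.cv_percent)
```

`dropfreq monitor` reports one row per time window for long recordings,
`dropfreq stream` replays a clip through the 5,000-frame FIFO real-time
pipeline, and `dropfreq compose` builds multi-channel composites.

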