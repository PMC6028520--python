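"""Synthetic droplet-generation video with known ground truth.

The generator emulates what a high-speed camera sees above a flow-focusing
nozzle: a bright microfluidic channel crossing the field of view, dark
droplets born at the (off-screen) nozzle at a scheduled instantaneous rate
and advected along the channel at constant speed, optional Gaussian pixel
noise, and a static background.  It reproduces the *periodic reappearance*
of the frame content that the cosine-similarity pipeline measures; it makes
no attempt at fluid dynamics (break-up regimes, droplet deformation,
coalescence), and disturbances are modelled as piecewise-constant steps of
the generation frequency.

Droplet centre-to-centre spacing is fixed, so advection speed equals
``spacing * frequency`` and a jitter-free constant-frequency clip is exactly
periodic in continuous time with period ``1/frequency``.

Geometric composition of several single-channel clips into one multi-channel
clip (vertical stacking, or zoom/rotate placement on a square canvas)
mirrors how multi-channel footage is cut together in a video editor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi

from .errors import (
    AlignmentError,
    InsufficientDataError,
    ParameterError,
)
from .video_io import FrameStack

#: Canonical camera resolution (rows, cols) of the single-channel videos.
DEFAULT_RESOLUTION = (62, 512)


@dataclass(frozen=True)
class SyntheticVideoConfig:
    """Generative specification for one synthetic single-channel clip.

    ``frequency_schedule`` is a list of ``(start_s, end_s, frequency_hz)``
    segments that must tile ``[0, n_frames / frame_rate]`` without gaps or
    overlaps.  ``spacing_px`` is the droplet centre-to-centre distance;
    advection speed is ``spacing_px * frequency``.  ``jitter`` is the
    fractional standard deviation of inter-droplet intervals.  All pixel
    intensities are on a nominal 8-bit-like scale, but only relative contrast
    matters downstream.
    """

    frequency_schedule: tuple[tuple[float, float, float], ...]
    frame_rate: float
    n_frames: int
    seed: int
    resolution: tuple[int, int] = DEFAULT_RESOLUTION
    channel_width: int = 40
    channel_axis_deg: float = 0.0
    droplet_diameter: float = 20.0
    contrast: float = 120.0
    spacing_px: float = 40.0
    jitter: float = 0.0
    noise_sigma: float = 2.0
    background: float = 160.0
    channel_intensity: float = 230.0
    wall_intensity: float = 60.0

    @classmethod
    def stable(cls, frequency_hz: float, frame_rate: float, n_frames: int,
               seed: int, **kwargs) -> "SyntheticVideoConfig":
        """Config for a constant-frequency clip covering the whole duration."""
        duration = n_frames / frame_rate
        return cls(
            frequency_schedule=((0.0, duration, float(frequency_hz)),),
            frame_rate=frame_rate,
            n_frames=n_frames,
            seed=seed,
            **kwargs,
        )

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if not self.frame_rate > 0:
            raise ParameterError("frame_rate must be > 0")
        sched = tuple(
            (float(a), float(b), float(f)) for a, b, f in self.frequency_schedule
        )
        object.__setattr__(self, "frequency_schedule", sched)
        if not sched:
            raise ParameterError("frequency_schedule is empty")
        duration = self.n_frames / self.frame_rate
        eps = 1e-9 * max(1.0, duration)
        if sched[0][0] > eps or sched[-1][1] < duration - eps:
            raise ParameterError(
                f"schedule must cover [0, {duration:.6g}] s without gaps"
            )
        for (a0, b0, _), (a1, _, _) in zip(sched, sched[1:]):
            if abs(b0 - a1) > eps:
                raise ParameterError("schedule segments must be contiguous")
        for a, b, f in sched:
            if b <= a:
                raise ParameterError(f"empty schedule segment ({a}, {b})")
            if not 0 < f < self.frame_rate / 2:
                raise ParameterError(
                    f"scheduled frequency {f} Hz violates Nyquist at "
                    f"{self.frame_rate} fps"
                )
        fmax = max(f for _, _, f in sched)
        if self.frame_rate < 5 * fmax:
            warnings.warn(
                f"frame rate {self.frame_rate} fps is below 5x the maximum "
                f"scheduled frequency {fmax} Hz; estimates may degrade",
                UserWarning,
                stacklevel=2,
            )
        m, n = self.resolution
        if not self.droplet_diameter < self.channel_width <= min(m, n):
            raise ParameterError(
                "need droplet_diameter < channel_width <= min(resolution)"
            )
        if self.spacing_px <= self.droplet_diameter:
            raise ParameterError("spacing_px must exceed droplet_diameter")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth: droplet birth times and instantaneous frequency.

    ``birth_times`` includes pre-roll births (negative times) used to
    populate the channel before the clip starts.  ``instantaneous_freq_hz``
    has one entry per frame.
    """

    birth_times: np.ndarray
    instantaneous_freq_hz: np.ndarray
    frame_rate: float


def _schedule_phase(config: SyntheticVideoConfig):
    """Piecewise-linear cumulative phase Phi(t) = integral of f, any real t."""
    sched = config.frequency_schedule
    knots_t = [sched[0][0]]
    knots_phi = [0.0]
    for a, b, f in sched:
        knots_t.append(b)
        knots_phi.append(knots_phi[-1] + f * (b - a))
    knots_t = np.asarray(knots_t)
    knots_phi = np.asarray(knots_phi)
    f_first = sched[0][2]
    f_last = sched[-1][2]

    def phi(t):
        t = np.asarray(t, dtype=np.float64)
        out = np.interp(t, knots_t, knots_phi)
        before = t < knots_t[0]
        after = t > knots_t[-1]
        out = np.where(before, f_first * (t - knots_t[0]), out)
        out = np.where(after, knots_phi[-1] + f_last * (t - knots_t[-1]), out)
        return out

    return phi


def _frequency_at(config: SyntheticVideoConfig, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    out = np.full(t.shape, config.frequency_schedule[0][2])
    for a, b, f in config.frequency_schedule:
        out = np.where((t >= a) & (t < b), f, out)
    out = np.where(t >= config.frequency_schedule[-1][1],
                   config.frequency_schedule[-1][2], out)
    return out


def _birth_times(config: SyntheticVideoConfig, rng: np.random.Generator) -> np.ndarray:
    """Droplet birth times from pre-roll through the end of the clip.

    Pre-roll starts early enough that the channel is fully populated at t=0.
    Jitter-free segments are generated by direct indexing (not interval
    accumulation) so constant-frequency clips are exactly periodic.
    """
    m, n = config.resolution
    f0 = config.frequency_schedule[0][2]
    travel_px = n + config.droplet_diameter + config.spacing_px
    t_start = -travel_px / (config.spacing_px * f0)

    births: list[np.ndarray] = []
    t_next = t_start
    segments = [(t_start, config.frequency_schedule[0][0], f0)]
    segments += list(config.frequency_schedule)
    for a, b, f in segments:
        if b <= t_next:
            continue
        if config.jitter == 0.0:
            count = int(np.floor((b - t_next) * f)) + 1
            seg = t_next + np.arange(count) / f
            seg = seg[seg < b]
            if seg.size:
                births.append(seg)
                t_next = seg[-1] + 1.0 / f
        else:
            seg = []
            while t_next < b:
                seg.append(t_next)
                factor = max(0.05, 1.0 + config.jitter * rng.standard_normal())
                t_next += factor / f
            if seg:
                births.append(np.asarray(seg))
    return np.concatenate(births) if births else np.empty(0)


def _static_background(config: SyntheticVideoConfig) -> np.ndarray:
    m, n = config.resolution
    frame = np.full((m, n), config.background, dtype=np.float64)
    cy = m // 2
    half = config.channel_width // 2
    top = cy - half
    bot = cy + (config.channel_width - half)
    frame[top:bot, :] = config.channel_intensity
    if top - 2 >= 0:
        frame[top - 2:top, :] = config.wall_intensity
    frame[bot:min(m, bot + 2), :] = config.wall_intensity
    return frame


def generate_video(config: SyntheticVideoConfig) -> tuple[FrameStack, GroundTruth]:
    """Render the clip described by ``config`` and return it with its truth.

    Deterministic given the seed: jitter and pixel noise draw from one
    seeded generator in a fixed order.
    """
    rng = np.random.default_rng(config.seed)
    m, n = config.resolution
    births = _birth_times(config, rng)
    phi = _schedule_phase(config)
    t_frames = np.arange(config.n_frames) / config.frame_rate
    phi_frames = phi(t_frames)
    phi_births = phi(births)

    r = config.droplet_diameter / 2.0
    cy = m // 2 - 0.5 + (config.channel_width % 2) / 2.0
    margin = r + 1.5

    template = _static_background(config)
    frames = np.empty((config.n_frames, m, n), dtype=np.float32)

    # droplet k is visible in frame j iff its x-position is within the frame;
    # x decreases with birth phase, so visible births are a contiguous slice
    lo_phase = phi_frames - (n + margin + r) / config.spacing_px
    hi_phase = phi_frames + margin / config.spacing_px
    lo_idx = np.searchsorted(phi_births, lo_phase, side="left")
    hi_idx = np.searchsorted(phi_births, hi_phase, side="right")

    row0 = max(0, int(np.floor(cy - r - 1)))
    row1 = min(m, int(np.ceil(cy + r + 2)))
    row_dist = np.arange(row0, row1, dtype=np.float64) - cy
    cols = np.arange(n, dtype=np.float64)

    # droplets are disjoint (spacing > diameter), so the anti-aliased disk
    # coverage at a pixel is governed by the nearest droplet centre alone
    for j in range(config.n_frames):
        frame = template.copy()
        xs = config.spacing_px * (phi_frames[j] - phi_births[lo_idx[j]:hi_idx[j]]) - r
        xs = xs[(xs >= -margin) & (xs <= n - 1 + margin)]
        if xs.size:
            dx = np.abs(cols[None, :] - xs[:, None]).min(axis=0)
            dist = np.hypot(row_dist[:, None], dx[None, :])
            coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)
            frame[row0:row1, :] -= config.contrast * coverage
        frames[j] = frame

    if config.channel_axis_deg != 0.0:
        rot = np.deg2rad(config.channel_axis_deg)
        mat = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        center = (np.asarray([m, n]) - 1) / 2.0
        offset = center - mat @ center
        for j in range(config.n_frames):
            frames[j] = _ndi.affine_transform(
                frames[j], mat, offset=offset, order=1, cval=config.background
            )

    if config.noise_sigma > 0:
        noise = rng.standard_normal(size=frames.shape, dtype=np.float32)
        frames += np.float32(config.noise_sigma) * noise
    np.clip(frames, 0.0, None, out=frames)

    truth = GroundTruth(
        birth_times=births,
        instantaneous_freq_hz=_frequency_at(config, t_frames),
        frame_rate=config.frame_rate,
    )
    return FrameStack(frames=frames, frame_rate=config.frame_rate), truth


def truth_statistics(
    gt: GroundTruth, window: tuple[float, float]
) -> tuple[float, float]:
    """True mean frequency (Hz) and interval CV (%) over a time window.

    Mean = number of inter-droplet intervals / summed interval time;
    CV = 100 * std/mean of the intervals.  Needs at least two births in the
    window.
    """
    w0, w1 = window
    births = gt.birth_times
    inside = births[(births >= w0) & (births <= w1)]
    if inside.size < 2:
        raise InsufficientDataError(
            f"window ({w0}, {w1}) contains {inside.size} droplet births; "
            "need at least 2"
        )
    intervals = np.diff(inside)
    mean_hz = intervals.size / float(intervals.sum())
    cv = 100.0 * float(np.std(intervals)) / float(np.mean(intervals))
    return mean_hz, cv


# ---------------------------------------------------------------------------
# multi-channel composition


def _channel_transform(zoom: float, rotation_deg: float,
                       src_shape: tuple[int, int],
                       anchor: tuple[float, float]):
    """Inverse affine map (canvas -> source) for one composed channel."""
    if zoom <= 0:
        raise ParameterError(f"zoom must be positive, got {zoom}")
    rot = np.deg2rad(rotation_deg)
    rot_inv = np.array([[np.cos(rot), np.sin(rot)],
                        [-np.sin(rot), np.cos(rot)]])
    matrix = rot_inv / zoom
    center_src = (np.asarray(src_shape, dtype=np.float64) - 1) / 2.0
    offset = center_src - matrix @ np.asarray(anchor, dtype=np.float64)
    return matrix, offset


def compose_multichannel(
    clips: list[FrameStack],
    zooms: list[float] | None = None,
    rotations: list[float] | None = None,
    layout: str = "vstack",
    canvas: tuple[int, int] = (512, 512),
    anchors: list[tuple[float, float]] | None = None,
) -> FrameStack:
    """Assemble single-channel clips into one multi-channel clip.

    ``vstack`` stacks equal-width clips vertically (parallel channels);
    ``canvas`` zooms then rotates each clip (bilinear, zero fill) and paints
    it onto a blank canvas at its anchor, later channels over earlier ones,
    emulating video-editor layering.  Zooms are scale factors (1.1 = 110%).
    """
    if not clips:
        raise AlignmentError("no clips to compose")
    n_frames = clips[0].n_frames
    frame_rate = clips[0].frame_rate
    for clip in clips[1:]:
        if clip.n_frames != n_frames:
            raise AlignmentError(
                f"frame-count mismatch: {clip.n_frames} vs {n_frames}"
            )
        if clip.frame_rate != frame_rate:
            raise AlignmentError(
                f"frame-rate mismatch: {clip.frame_rate} vs {frame_rate}"
            )

    if layout == "vstack":
        widths = {c.width for c in clips}
        if len(widths) != 1:
            raise AlignmentError(f"vstack needs equal widths, got {widths}")
        stacked = np.concatenate([c.frames for c in clips], axis=1)
        return FrameStack(frames=stacked, frame_rate=frame_rate)

    if layout != "canvas":
        raise ParameterError(f"unknown layout {layout!r} (vstack or canvas)")

    k = len(clips)
    zooms = list(zooms) if zooms is not None else [1.0] * k
    rotations = list(rotations) if rotations is not None else [0.0] * k
    if len(zooms) != k or len(rotations) != k:
        raise AlignmentError("zooms/rotations must match the number of clips")
    if anchors is None:
        anchors = [((i + 0.5) * canvas[0] / k, canvas[1] / 2.0) for i in range(k)]

    transforms = []
    for clip, zoom, rotation, anchor in zip(clips, zooms, rotations, anchors):
        matrix, offset = _channel_transform(
            zoom, rotation, (clip.height, clip.width), anchor
        )
        mask = _ndi.affine_transform(
            np.ones((clip.height, clip.width)), matrix, offset=offset,
            output_shape=canvas, order=1, cval=0.0,
        ) > 0.5
        transforms.append((matrix, offset, mask))

    out = np.zeros((n_frames, *canvas), dtype=np.float32)
    for clip, (matrix, offset, mask) in zip(clips, transforms):
        for j in range(n_frames):
            warped = _ndi.affine_transform(
                clip.frames[j].astype(np.float64), matrix, offset=offset,
                output_shape=canvas, order=1, cval=0.0,
            )
            out[j][mask] = warped[mask]
    return FrameStack(frames=out, frame_rate=frame_rate)
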