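"""Streaming (FIFO-buffered) and interval-based monitoring.

Real-time operation keeps two index-aligned FIFO buffers of capacity N
(default 5,000): the most recent frames and their cosine similarities
against a reference frame fixed at stream initialisation.  Until the buffer
first fills the stream is in a *build-up* phase — estimates are available
but provisional, with spectral resolution ``frame_rate / frames_buffered``
coarser than at capacity.  Once full it switches to the *real-time* phase:
admitting frame N+1 evicts frame 1 (and its similarity) from both buffers.

Because the reference vector is normalised once, each push costs exactly one
dot product of length R (the pixel count), independent of buffer length —
the saving that makes per-frame updates real-time-capable.  The spectrum is
recomputed from the whole buffer on demand; at N = 5,000 the FFT is a
negligible fraction of the per-update cost.

``monitor_process`` is the coarser online mode: the stream is cut into
windows of fixed length and each window is analysed by the batch pipeline
with that window's first frame as reference.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .core import SimilarityVector, similarity_to_reference, unit_reference_vector
from .errors import DimensionError, InsufficientDataError, ParameterError
from .pipeline import estimate_clip
from .spectral import (
    DEFAULT_PEAK_SNR,
    FrequencyEstimate,
    compute_auto_spectrum,
    estimate_frequency,
    find_fundamental_band,
)
from .video_io import FrameStack

#: Default FIFO capacity, matching a 5,000-frame clip.
DEFAULT_CAPACITY = 5000

#: Minimum buffer capacity / minimum similarities for an estimate.
MIN_CAPACITY = 16


@dataclass
class StreamState:
    """Paired FIFO buffers of frames and similarities plus the fixed reference.

    ``total_dot_ops`` accumulates the length of every dot product performed,
    so per-push cost can be asserted by operation count rather than clock.
    """

    reference_unit: np.ndarray
    capacity: int
    frame_rate: float
    frame_buffer: deque = field(default_factory=deque)
    similarity_buffer: deque = field(default_factory=deque)
    frames_seen: int = 0
    total_dot_ops: int = 0

    @property
    def phase(self) -> str:
        return "build_up" if self.frames_seen < self.capacity else "real_time"

    def __len__(self) -> int:
        return len(self.similarity_buffer)


def init_stream(
    reference_frame: np.ndarray,
    capacity: int = DEFAULT_CAPACITY,
    frame_rate: float = 1.0,
) -> StreamState:
    """Set up empty FIFO buffers and normalise the reference frame once."""
    if capacity < MIN_CAPACITY:
        raise ParameterError(f"capacity must be >= {MIN_CAPACITY}, got {capacity}")
    if not frame_rate > 0:
        raise ParameterError(f"frame_rate must be > 0, got {frame_rate}")
    ref_unit = unit_reference_vector(np.asarray(reference_frame))
    return StreamState(
        reference_unit=ref_unit,
        capacity=int(capacity),
        frame_rate=float(frame_rate),
        frame_buffer=deque(maxlen=int(capacity)),
        similarity_buffer=deque(maxlen=int(capacity)),
    )


def push_frame(state: StreamState, frame: np.ndarray) -> StreamState:
    """Admit one frame: append its similarity, evicting the oldest pair iff full.

    Cost: one dot product of length R against the cached unit reference.
    """
    frame = np.asarray(frame)
    if frame.size != state.reference_unit.size:
        raise DimensionError(
            f"frame has {frame.size} pixels, reference has "
            f"{state.reference_unit.size}"
        )
    sim = similarity_to_reference(frame, state.reference_unit, state.frames_seen)
    state.frame_buffer.append(frame)       # deque(maxlen) evicts oldest iff full
    state.similarity_buffer.append(sim)
    state.frames_seen += 1
    state.total_dot_ops += state.reference_unit.size
    return state


def rereference(state: StreamState, reference_frame: np.ndarray) -> StreamState:
    """Re-designate the reference frame and recompute buffered similarities.

    Useful after a large regime change, when the original reference may no
    longer match any recurring frame (peak power collapses).  Costs one dot
    product per buffered frame.
    """
    state.reference_unit = unit_reference_vector(np.asarray(reference_frame))
    sims = [
        similarity_to_reference(f, state.reference_unit, i)
        for i, f in enumerate(state.frame_buffer)
    ]
    state.similarity_buffer = deque(sims, maxlen=state.capacity)
    state.total_dot_ops += state.reference_unit.size * len(sims)
    return state


def stream_estimate(
    state: StreamState,
    *,
    window: str = "hann",
    prominence_frac: float = 0.5,
    peak_snr: float = DEFAULT_PEAK_SNR,
) -> FrequencyEstimate:
    """Estimate from the current similarity buffer.

    Identical to the batch pipeline on the buffered frames (bit-for-bit when
    the reference matches).  During build-up the result is flagged
    provisional: with fewer samples the spectral resolution
    ``frame_rate / n`` is proportionally coarser.
    """
    n = len(state.similarity_buffer)
    if n < MIN_CAPACITY:
        raise InsufficientDataError(
            f"only {n} similarities buffered; need {MIN_CAPACITY}"
        )
    sv = SimilarityVector(
        similarities=np.asarray(state.similarity_buffer, dtype=np.float64),
        reference_index=None,
        frame_rate=state.frame_rate,
    )
    spec = compute_auto_spectrum(sv, window=window)
    band = find_fundamental_band(spec, prominence_frac, peak_snr)
    est = estimate_frequency(spec, band)
    if state.phase == "build_up":
        est = replace(est, provisional=True)
    return est


@dataclass
class MonitorReport:
    """Chronological per-window estimates of a monitored process."""

    windows: list[tuple[float, float, FrequencyEstimate]]
    interval_s: float

    def mean_frequencies(self) -> np.ndarray:
        return np.asarray([est.mean_freq_hz for _, _, est in self.windows])

    def cvs(self) -> np.ndarray:
        return np.asarray([est.cv_percent for _, _, est in self.windows])


def _iter_frames(source) -> tuple[Iterator[np.ndarray], float | None]:
    if isinstance(source, FrameStack):
        return iter(source.frames), source.frame_rate
    return iter(source), None


def monitor_process(
    source: FrameStack | Iterable[np.ndarray],
    window_frames: int,
    interval_frames: int | None = None,
    frame_rate: float | None = None,
    *,
    window: str = "hann",
    prominence_frac: float = 0.5,
    peak_snr: float = DEFAULT_PEAK_SNR,
) -> MonitorReport:
    """Cut a stream into windows and analyse each with the batch pipeline.

    A window of ``window_frames`` starts every ``interval_frames`` (default:
    non-overlapping, interval = window).  Each window's first frame is its
    reference, so a regime change between windows cannot strand the whole
    report on a stale reference.  ``frame_rate`` is taken from the
    :class:`FrameStack` when one is given.
    """
    if window_frames < MIN_CAPACITY:
        raise ParameterError(f"window_frames must be >= {MIN_CAPACITY}")
    if interval_frames is None:
        interval_frames = window_frames
    if interval_frames < 1:
        raise ParameterError("interval_frames must be >= 1")
    frames, native_rate = _iter_frames(source)
    rate = frame_rate if frame_rate is not None else native_rate
    if rate is None or not rate > 0:
        raise ParameterError("frame_rate is required for frame iterators")

    buffer: deque = deque(maxlen=window_frames)
    results: list[tuple[float, float, FrequencyEstimate]] = []
    for i, frame in enumerate(frames):
        buffer.append(np.asarray(frame))
        n_seen = i + 1
        if n_seen >= window_frames and (n_seen - window_frames) % interval_frames == 0:
            stack = FrameStack(frames=np.stack(buffer), frame_rate=rate)
            est = estimate_clip(
                stack, 0, window=window,
                prominence_frac=prominence_frac, peak_snr=peak_snr,
            )
            start = (n_seen - window_frames) / rate
            results.append((start, n_seen / rate, est))
    if not results:
        raise InsufficientDataError(
            f"stream shorter than one window of {window_frames} frames"
        )
    return MonitorReport(windows=results, interval_s=interval_frames / rate)
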