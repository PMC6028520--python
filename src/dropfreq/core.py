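"""Cosine similarity between video frames: the periodic observable.

A grayscale frame of m rows and n columns is unrolled into a vector by
listing, for each column in turn, all of that column's rows (column-major
order).  The cosine similarity between a designated reference frame and every
frame of the clip, in time order, forms the *similarity vector* — a signal
that oscillates at the droplet-generation frequency because a stable
generation process makes the reference configuration reappear periodically.

Similarities are computed in double precision.  The reference vector is
normalised once and reused, so each frame costs a single dot product of
length m*n — the property the streaming layer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError, ZeroVectorError
from .video_io import FrameStack


@dataclass(frozen=True)
class GrayscaleVector:
    """A flattened frame: column-major pixel intensities plus its frame index."""

    values: np.ndarray
    source_index: int

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class SimilarityVector:
    """Per-frame cosine similarity against one reference frame.

    ``reference_index`` is None when the reference frame is not part of the
    sequence (e.g. it was evicted from a streaming buffer).
    """

    similarities: np.ndarray
    reference_index: int | None
    frame_rate: float

    def __post_init__(self) -> None:
        sims = np.asarray(self.similarities, dtype=np.float64)
        object.__setattr__(self, "similarities", sims)
        if self.reference_index is not None and not (
            0 <= self.reference_index < sims.size
        ):
            raise ParameterError(
                f"reference_index {self.reference_index} outside [0, {sims.size})"
            )

    def __len__(self) -> int:
        return self.similarities.size


def flatten_frame(frame: np.ndarray, index: int = 0) -> GrayscaleVector:
    """Unroll a 2-D grayscale frame into its column-major grayscale vector.

    Element ``k`` of the result is the pixel at column ``k // m``, row
    ``k % m`` (0-based), i.e. column 1 top-to-bottom, then column 2, and so
    on.  All-zero frames are rejected: the cosine of an angle with the zero
    vector is undefined.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size < 1:
        raise DimensionError(f"expected a 2-D frame, got shape {frame.shape}")
    values = frame.flatten(order="F").astype(np.float64)
    if not np.any(values):
        raise ZeroVectorError(
            f"frame {index} is all-zero; cosine similarity is undefined"
        )
    return GrayscaleVector(values=values, source_index=int(index))


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two non-zero vectors: a.b / (|a||b|).

    Symmetric and invariant to positive rescaling of either argument; the
    result lies in [-1, 1], and in [0, 1] for non-negative intensities.
    """
    va = a.values if isinstance(a, GrayscaleVector) else np.asarray(a, dtype=np.float64)
    vb = b.values if isinstance(b, GrayscaleVector) else np.asarray(b, dtype=np.float64)
    if va.shape != vb.shape:
        raise DimensionError(f"length mismatch: {va.shape} vs {vb.shape}")
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ZeroVectorError("cosine similarity is undefined for zero vectors")
    return float(np.dot(va, vb) / (na * nb))


def unit_reference_vector(reference_frame: np.ndarray, index: int = 0) -> np.ndarray:
    """Flatten and L2-normalise a reference frame (normalised exactly once)."""
    ref = flatten_frame(reference_frame, index)
    return ref.values / ref.norm


def similarity_to_reference(
    frame: np.ndarray, ref_unit: np.ndarray, index: int = 0
) -> float:
    """Cosine similarity of one frame against a pre-normalised reference.

    This single code path is shared by the batch and streaming pipelines so
    that both produce bit-identical similarity values.
    """
    flat = flatten_frame(frame, index)
    if flat.values.shape != ref_unit.shape:
        raise DimensionError(
            f"frame {index} flattens to length {flat.values.size}, "
            f"reference has length {ref_unit.size}"
        )
    return float(np.dot(flat.values, ref_unit) / flat.norm)


def crop_roi(stack: FrameStack, roi: tuple[int, int, int, int]) -> FrameStack:
    """Crop a rectangular region (row0, row1, col0, col1) from every frame."""
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= stack.height and 0 <= c0 < c1 <= stack.width):
        raise ParameterError(f"ROI {roi} outside frame bounds "
                             f"{stack.height}x{stack.width}")
    return FrameStack(frames=stack.frames[:, r0:r1, c0:c1],
                      frame_rate=stack.frame_rate)


def build_similarity_vector(
    stack: FrameStack, reference_index: int = 0
) -> SimilarityVector:
    """Compute the similarity vector of a clip against one of its frames.

    The reference defaults to the first frame.  The entry at the reference
    index is 1 (to within double-precision rounding).  Any all-zero frame
    aborts with an error naming the frame: a black frame signals acquisition
    failure, and skipping it silently would corrupt the time base.
    """
    if not 0 <= reference_index < stack.n_frames:
        raise ParameterError(
            f"reference_index {reference_index} outside [0, {stack.n_frames})"
        )
    ref_unit = unit_reference_vector(stack.frames[reference_index], reference_index)
    sims = np.empty(stack.n_frames, dtype=np.float64)
    for i, frame in enumerate(stack.frames):
        sims[i] = similarity_to_reference(frame, ref_unit, i)
    return SimilarityVector(
        similarities=sims,
        reference_index=reference_index,
        frame_rate=stack.frame_rate,
    )
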