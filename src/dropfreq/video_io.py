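"""Reading and writing grayscale video frame stacks and analysis reports.

The canonical in-memory representation is :class:`FrameStack`: a dense
``(n_frames, height, width)`` float32 array plus the capture frame rate.
High-speed captures are routinely re-wrapped at playback frame rates, so the
true acquisition rate is always supplied by the caller and never read from
container metadata.

Lossless persistence uses TIFF (a single multi-page file or a directory of
numbered single-page files), which round-trips float pixel data exactly.
Directories of numbered PNG frames are read for integer-valued user data.
AVI files are delegated to imageio and require an ffmpeg backend.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    FormatError,
    InvariantError,
    ParameterError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .online import MonitorReport
    from .spectral import FrequencyEstimate, MultiChannelEstimate

#: ITU-R BT.601 luma weights used to collapse colour inputs to grayscale.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: File suffixes accepted inside a frame directory, in lexicographic read order.
_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}

#: Exact column order of CSV reports.
REPORT_COLUMNS = (
    "window_start_s",
    "window_end_s",
    "mean_freq_hz",
    "cv_percent",
    "peak_power",
    "n_frames",
)


@dataclass(frozen=True)
class FrameStack:
    """An ordered stack of same-resolution grayscale frames at a constant rate.

    Parameters
    ----------
    frames:
        Array of shape ``(n_frames, height, width)``; intensities are
        non-negative linear units.  The absolute scale is irrelevant
        downstream because cosine similarity is scale invariant.
    frame_rate:
        Acquisition rate in frames per second (Hz), strictly positive.
    """

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise InvariantError(
                f"frames must be (n_frames, height, width), got shape {frames.shape}"
            )
        if frames.shape[0] < 2:
            raise InvariantError("a frame stack needs at least 2 frames")
        if not self.frame_rate > 0:
            raise ParameterError(f"frame_rate must be > 0, got {self.frame_rate}")
        if np.any(frames < 0):
            raise InvariantError("pixel intensities must be non-negative")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        """Number of pixel rows (m)."""
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        """Number of pixel columns (n)."""
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def __len__(self) -> int:
        return self.n_frames


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an ``(h, w)`` or ``(h, w, 3|4)`` image to 2-D grayscale.

    Already-grayscale input is returned unchanged (identity).  Colour input is
    reduced with BT.601 luma weights; any fixed linear map preserves the
    temporal periodicity the pipeline measures, so the exact weights are a
    convention, not a tunable.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        rgb = image[..., :3].astype(np.float64)
        return rgb @ np.asarray(LUMA_WEIGHTS)
    raise FormatError(f"cannot interpret image of shape {image.shape} as grayscale")


def _list_frame_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in _FRAME_SUFFIXES and p.is_file()
    )
    if not files:
        raise EmptyInputError(f"no PNG/TIFF frames found in {directory}")
    return files


def _read_avi(path: Path, max_frames: int | None) -> list[np.ndarray]:
    import imageio.v3 as iio

    try:
        frames = []
        for i, frame in enumerate(iio.imiter(path, plugin="pyav")):
            if max_frames is not None and i >= max_frames:
                break
            frames.append(to_grayscale(frame))
        return frames
    except ImportError as exc:
        raise FormatError(
            "reading AVI requires an ffmpeg/pyav backend for imageio, which is "
            "not installed; use a TIFF stack or a PNG/TIFF frame directory"
        ) from exc
    except Exception as exc:  # unreadable container
        raise FormatError(f"could not decode {path}: {exc}") from exc


def read_video(
    path: str | os.PathLike,
    frame_rate: float,
    max_frames: int | None = None,
) -> FrameStack:
    """Read a video into a :class:`FrameStack`.

    ``path`` may be a directory of numbered PNG/TIFF frames (lexicographic
    order), a multi-page TIFF, or an AVI file.  ``frame_rate`` is the true
    acquisition rate and must be supplied by the caller.  At most
    ``max_frames`` frames are kept, counted from the start.
    """
    path = Path(path)
    if not frame_rate > 0:
        raise ParameterError(f"frame_rate must be > 0, got {frame_rate}")
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")

    if path.is_dir():
        import imageio.v3 as iio
        import tifffile

        files = _list_frame_files(path)
        if max_frames is not None:
            files = files[:max_frames]
        frames = []
        for f in files:
            if f.suffix.lower() in (".tif", ".tiff"):
                img = tifffile.imread(f)
            else:
                img = iio.imread(f)
            frames.append(to_grayscale(img))
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        frames = [to_grayscale(f) for f in data]
        if max_frames is not None:
            frames = frames[:max_frames]
    elif path.suffix.lower() == ".avi":
        frames = _read_avi(path, max_frames)
    else:
        raise FormatError(f"unsupported video container: {path}")

    if not frames:
        raise EmptyInputError(f"no frames read from {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise InvariantError(f"frames have mixed resolutions: {sorted(shapes)}")
    stack = np.stack([np.asarray(f, dtype=np.float32) for f in frames])
    return FrameStack(frames=stack, frame_rate=float(frame_rate))


def write_video(stack: FrameStack, path: str | os.PathLike) -> Path:
    """Write a frame stack losslessly.

    ``*.tif``/``*.tiff`` produces a single multi-page TIFF; any other path is
    created as a directory of numbered single-page TIFF frames.  Both
    round-trip pixel values exactly through :func:`read_video`.
    """
    if not isinstance(stack, FrameStack):
        raise ParameterError("write_video expects a FrameStack")
    path = Path(path)
    import tifffile

    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            path.parent.mkdir(parents=True, exist_ok=True)
            tifffile.imwrite(path, stack.frames)
        else:
            path.mkdir(parents=True, exist_ok=True)
            ndigits = max(5, len(str(stack.n_frames)))
            for i, frame in enumerate(stack.frames):
                tifffile.imwrite(path / f"frame_{i:0{ndigits}d}.tif", frame)
    except OSError as exc:
        raise FormatError(f"could not write video to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# reports


def _estimate_row(
    est: "FrequencyEstimate", window_start_s: float, window_end_s: float
) -> dict:
    return {
        "window_start_s": float(window_start_s),
        "window_end_s": float(window_end_s),
        "mean_freq_hz": float(est.mean_freq_hz),
        "cv_percent": float(est.cv_percent),
        "peak_power": float(est.peak_power),
        "n_frames": int(est.n_frames),
    }


def report_rows(report) -> list[dict]:
    """Flatten an estimate / multi-channel estimate / monitor report to rows."""
    from .online import MonitorReport
    from .spectral import FrequencyEstimate, MultiChannelEstimate

    if isinstance(report, FrequencyEstimate):
        return [_estimate_row(report, 0.0, report.n_frames / report.frame_rate)]
    if isinstance(report, MultiChannelEstimate):
        return [
            _estimate_row(ch, 0.0, ch.n_frames / ch.frame_rate)
            for ch in report.channels
        ]
    if isinstance(report, MonitorReport):
        return [
            _estimate_row(est, start, end) for start, end, est in report.windows
        ]
    raise ParameterError(f"cannot serialize report of type {type(report).__name__}")


def write_report(
    report,
    path: str | os.PathLike,
    format: str = "csv",
    config: dict | None = None,
) -> Path:
    """Write an analysis result as CSV or JSON.

    CSV columns are exactly ``window_start_s, window_end_s, mean_freq_hz,
    cv_percent, peak_power, n_frames``; JSON mirrors the same fields and
    additionally embeds the resolved run ``config`` when one is supplied.
    """
    path = Path(path)
    rows = report_rows(report)
    if format == "csv":
        import pandas as pd

        frame = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, index=False, float_format="%.10g")
    elif format == "json":
        payload: dict = {"rows": rows}
        if config is not None:
            payload["config"] = config
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ParameterError(f"unknown report format: {format!r} (csv or json)")
    return path
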