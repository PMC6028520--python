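"""End-to-end batch analysis: frame stack in, frequency estimate out."""

from __future__ import annotations

from .core import build_similarity_vector
from .spectral import (
    DEFAULT_PEAK_SNR,
    FrequencyEstimate,
    MultiChannelEstimate,
    compute_auto_spectrum,
    detect_fundamentals,
    estimate_frequency,
    find_fundamental_band,
)
from .video_io import FrameStack


def estimate_clip(
    stack: FrameStack,
    reference_index: int = 0,
    *,
    window: str = "hann",
    prominence_frac: float = 0.5,
    peak_snr: float = DEFAULT_PEAK_SNR,
) -> FrequencyEstimate:
    """Single-channel pipeline: similarity vector -> spectrum -> estimate.

    The reference frame defaults to the first frame of the clip.
    """
    sv = build_similarity_vector(stack, reference_index)
    spec = compute_auto_spectrum(sv, window=window)
    band = find_fundamental_band(spec, prominence_frac, peak_snr)
    return estimate_frequency(spec, band)


def estimate_channels(
    stack: FrameStack,
    max_channels: int = 3,
    reference_index: int = 0,
    *,
    window: str = "hann",
    prominence_frac: float = 0.05,
    harmonic_tol: float = 0.02,
    peak_snr: float = DEFAULT_PEAK_SNR,
) -> MultiChannelEstimate:
    """Multi-channel pipeline: one run yields every channel's fundamental."""
    sv = build_similarity_vector(stack, reference_index)
    spec = compute_auto_spectrum(sv, window=window)
    return detect_fundamentals(
        spec,
        max_channels=max_channels,
        prominence_frac=prominence_frac,
        harmonic_tol=harmonic_tol,
        peak_snr=peak_snr,
    )
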