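"""Windowed spectral decomposition of iEEG clips.

A ten-minute clip is sliced into overlapping Hamming-tapered windows
(60 s window, 30 s step by default, giving 19 windows per 600 s clip).
Each window is zero-padded to the next power of two, Fourier transformed,
and reduced to the magnitude (or power) at the positive-frequency bins,
excluding DC.  Magnitudes are compressed with log1p, either directly on the
bins (``log_order='pre'``, the default) or deferred until after band
filtering (``log_order='post'``).

The six canonical EEG bands — delta (0.1-4 Hz), theta (4-8), alpha (8-12),
beta (12-30), low gamma (30-70) and high gamma (70-180) — are mapped to
half-open bin-index ranges on the DC-excluded frequency axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal.windows import hamming

from .iodata import IEEGClip


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds."""

    window_sec: float = 60.0
    step_sec: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.step_sec <= self.window_sec):
            raise ValueError(
                f"need 0 < step ({self.step_sec}) <= window ({self.window_sec})"
            )

    def count(self, duration_sec: float) -> int:
        """Number of full windows that fit in a clip of the given duration."""
        if duration_sec < self.window_sec:
            raise ValueError(
                f"clip of {duration_sec} s shorter than one {self.window_sec} s window"
            )
        return int(np.floor((duration_sec - self.window_sec) / self.step_sec)) + 1


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band as a half-open interval [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(f"bad band {self.name}: [{self.low_hz}, {self.high_hz})")


#: The six canonical EEG bands used throughout the pipeline.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.1, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("low_gamma", 30.0, 70.0),
    BandDefinition("high_gamma", 70.0, 180.0),
)


@dataclass
class SpectralTensor:
    """Per-window, per-channel spectra with their frequency axis.

    ``values`` has shape ``(windows, channels, bins)`` where
    ``bins == fft_length // 2`` and ``freq_hz[j] == (j + 1) * rate / fft_length``
    (DC excluded, Nyquist included).  ``log_applied`` records whether the
    bins already carry log1p compression.
    """

    values: np.ndarray
    freq_hz: np.ndarray
    window_starts_sec: np.ndarray
    sampling_rate_hz: float
    fft_length: int
    log_applied: bool = True

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be (windows, channels, bins)")
        if self.values.shape[2] != self.fft_length // 2:
            raise ValueError("bins != fft_length // 2")
        if self.freq_hz.shape != (self.values.shape[2],):
            raise ValueError("freq_hz length != bins")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]


def next_pow2(n: int) -> int:
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1 << (int(n) - 1).bit_length()


def sliding_windows(clip: IEEGClip, spec: WindowSpec = WindowSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Cut a clip into Hamming-tapered windows.

    Returns ``(tapered, starts)`` where ``tapered`` has shape
    ``(windows, channels, window_samples)`` and ``starts`` gives each
    window's start time in seconds.  The window count is
    ``floor((duration - window) / step) + 1``.
    """
    n_windows = spec.count(clip.duration_sec)
    window_samples = int(round(spec.window_sec * clip.sampling_rate_hz))
    step_samples = int(round(spec.step_sec * clip.sampling_rate_hz))
    taper = hamming(window_samples, sym=True)
    out = np.empty((n_windows, clip.n_channels, window_samples))
    starts = np.empty(n_windows)
    for w in range(n_windows):
        i0 = w * step_samples
        out[w] = clip.data[:, i0 : i0 + window_samples] * taper
        starts[w] = i0 / clip.sampling_rate_hz
    return out, starts


def log_spectrum(
    windows: np.ndarray,
    rate_hz: float,
    window_starts_sec: np.ndarray | None = None,
    spectrum: str = "magnitude",
    log_order: str = "pre",
) -> SpectralTensor:
    """FFT each tapered window and log-compress the positive-frequency bins.

    The FFT length is the smallest power of two at or above the window
    length (windows are zero-padded).  Bins 1..fft_length/2 are retained:
    DC is dropped, the Nyquist bin kept.  With ``log_order='pre'`` the
    returned values are ``log1p(magnitude)``; with ``'post'`` raw
    magnitudes are returned and the compression is applied downstream,
    after band filtering.
    """
    if windows.ndim != 3:
        raise ValueError("windows must be (windows, channels, samples)")
    window_samples = windows.shape[2]
    if window_samples < 2:
        raise ValueError("windows must have >= 2 samples")
    if spectrum not in ("magnitude", "power"):
        raise ValueError(f"unknown spectrum {spectrum!r}")
    if log_order not in ("pre", "post"):
        raise ValueError(f"unknown log_order {log_order!r}")
    n_fft = next_pow2(window_samples)
    # rfft of a zero-padded real window: bins 0..n_fft/2; drop bin 0 (DC).
    mag = np.abs(np.fft.rfft(windows, n=n_fft, axis=2)[:, :, 1:])
    if spectrum == "power":
        mag = mag**2
    values = np.log1p(mag) if log_order == "pre" else mag
    n_bins = n_fft // 2
    freq = (np.arange(n_bins) + 1) * rate_hz / n_fft
    if window_starts_sec is None:
        window_starts_sec = np.zeros(windows.shape[0])
    return SpectralTensor(
        values=values,
        freq_hz=freq,
        window_starts_sec=np.asarray(window_starts_sec, dtype=float),
        sampling_rate_hz=float(rate_hz),
        fft_length=n_fft,
        log_applied=(log_order == "pre"),
    )


def clip_spectrum(
    clip: IEEGClip,
    spec: WindowSpec = WindowSpec(),
    spectrum: str = "magnitude",
    log_order: str = "pre",
) -> SpectralTensor:
    """Convenience: sliding_windows followed by log_spectrum."""
    windows, starts = sliding_windows(clip, spec)
    return log_spectrum(windows, clip.sampling_rate_hz, starts, spectrum, log_order)


def band_bin_ranges(
    rate_hz: float,
    fft_length: int,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
) -> dict[str, slice]:
    """Map each band to a contiguous slice of the DC-excluded bin axis.

    Bin ``j`` (0-based) holds frequency ``(j + 1) * rate / fft_length``; a
    band claims the bins with ``low_hz <= f < high_hz``.  Bands lying above
    Nyquist come back as empty slices; if every requested band is empty the
    rate cannot support the analysis and an error is raised.
    """
    n_bins = fft_length // 2
    freq = (np.arange(n_bins) + 1) * rate_hz / fft_length
    ranges: dict[str, slice] = {}
    for band in bands:
        idx = np.nonzero((freq >= band.low_hz) & (freq < band.high_hz))[0]
        ranges[band.name] = slice(int(idx[0]), int(idx[-1]) + 1) if idx.size else slice(0, 0)
    if all(s.stop == s.start for s in ranges.values()):
        raise ValueError(
            f"no band has support below Nyquist ({rate_hz / 2} Hz) at fft_length {fft_length}"
        )
    return ranges


def band_sizes(ranges: dict[str, slice]) -> dict[str, int]:
    return {name: s.stop - s.start for name, s in ranges.items()}
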