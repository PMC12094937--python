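"""Windowing, preprocessing, and spectral primitives shared by all freeze-index estimators.

Every freeze-index (FI) definition reduces to the same recipe: slide a short
window along a gait proxy signal, estimate the window's power spectral
density (PSD), integrate it over a locomotion band and a freeze band, and map
the band-power ratio to a score.  This module provides the pieces of that
recipe — linear detrending, Slepian (DPSS) taper sets, multitaper and plain
periodogram PSD estimates, trapezoidal band-power integration, and the
logarithmic "Moore" normalization ``x -> ln(100 x)``.

Absolute PSD scaling is deliberately left arbitrary: the FI only ever uses
ratios of band powers, so all constant scalings (FFT normalization, division
by the taper count, one-sided doubling) cancel and are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sps
from scipy.fft import rfft, rfftfreq

__all__ = [
    "Signal",
    "PsdEstimate",
    "FrequencyBands",
    "TaperSet",
    "detrend_linear",
    "make_dpss_tapers",
    "default_nfft",
    "multitaper_psd",
    "periodogram_psd",
    "band_power",
    "moore_normalization",
]

#: Recognized window preprocessing modes for the plain periodogram.
PREPROCESS_MODES = ("none", "mean_subtract", "hann")


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples
        Sample values in any physical unit (e.g. mg or m/s^2).  The FI is
        invariant to the overall scale, so no unit conversion is performed.
    fs
        Sampling frequency in Hz.  Must be positive.
    t0
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("signal samples must be one-dimensional")
        if samples.size < 2:
            raise ValueError("signal must contain at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal samples must be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "t0", float(self.t0))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal span in seconds (N/fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample time stamps in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class PsdEstimate:
    """A one-sided spectral weight function on a uniform frequency grid.

    ``values`` carry an arbitrary overall scale — only ratios of band
    integrals are meaningful downstream.
    """

    freqs: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if freqs.ndim != 1 or values.ndim != 1 or freqs.size != values.size:
            raise ValueError("freqs and values must be 1-D arrays of equal length")
        if freqs.size < 2:
            raise ValueError("PSD grid must contain at least 2 nodes")
        df = np.diff(freqs)
        if not np.all(df > 0):
            raise ValueError("frequency grid must be strictly ascending")
        if not np.allclose(df, df[0], rtol=1e-9, atol=1e-12 * freqs[-1]):
            raise ValueError("frequency grid must be uniform")
        if np.any(values < 0):
            raise ValueError("PSD values must be nonnegative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class FrequencyBands:
    """Locomotion and freeze integration bands split at the threshold ``f_threshold``.

    Normal stepping concentrates spectral power below roughly 3 Hz while
    trembling-in-place during a freeze shifts power toward 3-8 Hz; the bands
    are ``[loco_lo, f_threshold]`` and ``[f_threshold, freeze_hi]`` Hz.
    """

    f_threshold: float = 3.0
    loco_lo: float = 0.5
    freeze_hi: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.loco_lo < self.f_threshold < self.freeze_hi):
            raise ValueError(
                "bands require 0 <= loco_lo < f_threshold < freeze_hi, got "
                f"{self.loco_lo}, {self.f_threshold}, {self.freeze_hi}"
            )

    @property
    def loco(self) -> tuple[float, float]:
        return (self.loco_lo, self.f_threshold)

    @property
    def freeze(self) -> tuple[float, float]:
        return (self.f_threshold, self.freeze_hi)


@dataclass(frozen=True)
class TaperSet:
    """A set of orthonormal Slepian (DPSS) tapers.

    ``tapers`` is an ``(L, n)`` array whose rows are pairwise orthonormal and
    ordered by decreasing spectral concentration in the normalized band
    ``|f| <= half_bandwidth / n`` (cycles per sample times window length).
    """

    tapers: np.ndarray
    half_bandwidth: float

    def __post_init__(self) -> None:
        tapers = np.atleast_2d(np.asarray(self.tapers, dtype=float))
        object.__setattr__(self, "tapers", tapers)

    @property
    def n_tapers(self) -> int:
        return self.tapers.shape[0]

    @property
    def n_samples(self) -> int:
        return self.tapers.shape[1]


def detrend_linear(window: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line from a window.

    The residual has zero mean and zero least-squares slope.  Applied before
    tapering so slow drifts (gravity re-orientation, sensor bias) do not leak
    into the locomotion band.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("detrend_linear requires a 1-D window of length >= 2")
    return _sps.detrend(window, type="linear")


def _detrend_rows(windows: np.ndarray) -> np.ndarray:
    """Vectorized linear detrend of each row of an ``(m, n)`` window matrix."""
    n = windows.shape[1]
    k = np.arange(n, dtype=float) - (n - 1) / 2.0
    centered = windows - windows.mean(axis=1, keepdims=True)
    slope = centered @ k / (k @ k)
    return centered - slope[:, None] * k


def make_dpss_tapers(n_samples: int, half_bandwidth: float = 2.5, n_tapers: int = 4) -> TaperSet:
    """Generate the first ``n_tapers`` orthonormal Slepian sequences.

    Parameters
    ----------
    n_samples
        Window length in samples.
    half_bandwidth
        Standardized half-bandwidth (the usual DPSS ``NW`` product).  Only
        the first ``floor(2 * half_bandwidth) - 1`` tapers are well
        concentrated; requesting more raises a ``ValueError``.
    n_tapers
        Number of tapers to return, ordered by decreasing concentration.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    max_tapers = int(np.floor(2 * half_bandwidth)) - 1
    if not (1 <= n_tapers <= max_tapers):
        raise ValueError(
            f"n_tapers must satisfy 1 <= n_tapers <= floor(2B)-1 = {max_tapers} "
            f"for half_bandwidth={half_bandwidth}; got {n_tapers}"
        )
    tapers = _sps.windows.dpss(n_samples, half_bandwidth, Kmax=n_tapers, sym=True)
    return TaperSet(tapers=tapers, half_bandwidth=float(half_bandwidth))


def default_nfft(n_samples: int) -> int:
    """Zero-padded FFT length: smallest power of two >= 4x the window length.

    Four-fold over-resolution makes band-edge discretization error negligible
    while keeping power-of-two FFT sizes.
    """
    nfft = 1
    while nfft < 4 * n_samples:
        nfft <<= 1
    return nfft


def multitaper_psd(
    window: np.ndarray,
    tapers: TaperSet,
    fs: float,
    nfft: int | None = None,
) -> PsdEstimate:
    """Unweighted multitaper spectral estimate of a (detrended) window.

    Each taper is applied to the window, the product zero-padded to ``nfft``
    and transformed; the squared magnitudes are summed over tapers.  No 1/L
    averaging and no FFT scaling are applied — both cancel in band-power
    ratios.
    """
    window = np.asarray(window, dtype=float)
    if window.size != tapers.n_samples:
        raise ValueError(
            f"window length {window.size} does not match taper length {tapers.n_samples}"
        )
    if nfft is None:
        nfft = default_nfft(window.size)
    if nfft < window.size:
        raise ValueError(f"nfft ({nfft}) must be >= window length ({window.size})")
    spectra = rfft(window[None, :] * tapers.tapers, n=nfft, axis=1)
    values = np.sum(np.abs(spectra) ** 2, axis=0)
    return PsdEstimate(freqs=rfftfreq(nfft, 1.0 / fs), values=values)


def periodogram_psd(
    window: np.ndarray,
    fs: float,
    preprocess: str = "none",
    nfft: int | None = None,
) -> PsdEstimate:
    """Plain squared-magnitude FFT periodogram with optional preprocessing.

    ``preprocess`` selects the historical window treatment: ``"none"`` (raw
    rectangular window), ``"mean_subtract"`` (subtract the window mean), or
    ``"hann"`` (multiply by a symmetric Hann window).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("periodogram_psd requires a 1-D window of length >= 2")
    if preprocess not in PREPROCESS_MODES:
        raise ValueError(
            f"unknown preprocess {preprocess!r}; expected one of {PREPROCESS_MODES}"
        )
    if nfft is None:
        nfft = default_nfft(window.size)
    if nfft < window.size:
        raise ValueError(f"nfft ({nfft}) must be >= window length ({window.size})")
    if preprocess == "mean_subtract":
        window = window - window.mean()
    elif preprocess == "hann":
        window = window * _sps.windows.hann(window.size, sym=True)
    values = np.abs(rfft(window, n=nfft)) ** 2
    return PsdEstimate(freqs=rfftfreq(nfft, 1.0 / fs), values=values)


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = float(band[0]), float(band[1])
    if not (0.0 <= lo < hi):
        raise ValueError(f"invalid band {band}")
    if hi > freqs[-1] * (1 + 1e-12):
        raise ValueError(
            f"band {band} exceeds the frequency grid (max {freqs[-1]:.4g} Hz)"
        )
    tol = 1e-9 * max(1.0, freqs[-1])
    mask = (freqs >= lo - tol) & (freqs <= hi + tol)
    if np.count_nonzero(mask) < 2:
        raise ValueError(
            f"fewer than 2 grid nodes fall inside band {band}; grid too coarse"
        )
    return mask


def band_power(psd: PsdEstimate, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over the grid nodes inside the closed band."""
    mask = _band_mask(psd.freqs, band)
    return float(np.trapezoid(psd.values[mask], psd.freqs[mask]))


def moore_normalization(x):
    """Logarithmic normalization ``x -> ln(100 x)`` of a positive band-power ratio.

    Maps the raw freeze/locomotion power ratio to the conventional FI scale;
    ``x = 0.01`` maps to 0.  Raises on nonpositive input — estimators convert
    degenerate (zero-power) windows to NaN before reaching this primitive.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("moore_normalization requires strictly positive input")
    out = np.log(100.0 * arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out
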