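"""Independent brute-force oracles used to validate the spectral pipeline.

Everything here deliberately avoids the library's own FFT/trapezoid/window
machinery: DFTs are explicit complex-exponential matrix products, least
squares goes through the normal equations, and integrals are summed term by
term.  Slow by construction — only for short fixtures.
"""

import numpy as np
from scipy.signal import windows as _w


def lstsq_line_residual(x):
    """Least-squares straight-line residual via the normal equations."""
    x = np.asarray(x, dtype=float)
    n = x.size
    A = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
    coef = np.linalg.solve(A.T @ A, A.T @ x)
    return x - A @ coef


def direct_dft_onesided(x, nfft, fs):
    """One-sided DFT by explicit matrix multiplication (no FFT)."""
    x = np.asarray(x, dtype=float)
    padded = np.zeros(nfft)
    padded[: x.size] = x
    k = np.arange(nfft // 2 + 1)
    n = np.arange(nfft)
    basis = np.exp(-2j * np.pi * np.outer(k, n) / nfft)
    return basis @ padded, k * fs / nfft


def trapezoid_sum(y, x):
    """Term-by-term trapezoidal rule."""
    total = 0.0
    for i in range(len(x) - 1):
        total += 0.5 * (y[i] + y[i + 1]) * (x[i + 1] - x[i])
    return total


def _next_pow2_4x(n):
    nfft = 1
    while nfft < 4 * n:
        nfft *= 2
    return nfft


def _band_nodes(freqs, band):
    tol = 1e-9 * max(1.0, freqs[-1])
    return [i for i, f in enumerate(freqs) if band[0] - tol <= f <= band[1] + tol]


def _band_ratio(psd, freqs, loco, freeze):
    loco_idx = _band_nodes(freqs, loco)
    freeze_idx = _band_nodes(freqs, freeze)
    p_loco = trapezoid_sum([psd[i] for i in loco_idx], [freqs[i] for i in loco_idx])
    p_freeze = trapezoid_sum([psd[i] for i in freeze_idx], [freqs[i] for i in freeze_idx])
    return p_freeze / p_loco


def fi_multitaper_oracle(signal, window=5.0, n_tapers=4, half_bandwidth=2.5, f_threshold=3.0, step=0.1):
    """From-scratch multitaper FI: python loops, matrix DFT, manual trapezoids."""
    x, fs = signal.samples, signal.fs
    n_win = int(np.floor(window * fs + 0.5))
    hop = max(1, int(np.floor(step * fs + 0.5)))
    nfft = _next_pow2_4x(n_win)
    tapers = _w.dpss(n_win, half_bandwidth, Kmax=n_tapers, sym=True)
    loco, freeze = (0.5, f_threshold), (f_threshold, 8.0)
    times, values = [], []
    start = 0
    while start + n_win <= x.size:
        w = lstsq_line_residual(x[start : start + n_win])
        psd = None
        for taper in tapers:
            spec, freqs = direct_dft_onesided(w * taper, nfft, fs)
            mag = np.abs(spec) ** 2
            psd = mag if psd is None else psd + mag
        values.append(np.log(100.0 * _band_ratio(psd, freqs, loco, freeze)))
        times.append(signal.t0 + (start + (n_win - 1) / 2.0) / fs)
        start += hop
    return np.asarray(times), np.asarray(values)


def fi_legacy_oracle(signal, window, step, loco, freeze, preprocess, square, normalize):
    """From-scratch legacy FI with explicit preprocessing and matrix DFT."""
    x, fs = signal.samples, signal.fs
    n_win = int(np.floor(window * fs + 0.5))
    hop = max(1, int(np.floor(step * fs + 0.5)))
    nfft = _next_pow2_4x(n_win)
    values = []
    start = 0
    while start + n_win <= x.size:
        w = np.array(x[start : start + n_win], dtype=float)
        if preprocess == "mean_subtract":
            w = w - w.mean()
        elif preprocess == "hann":
            w = w * _w.hann(n_win, sym=True)
        spec, freqs = direct_dft_onesided(w, nfft, fs)
        r = _band_ratio(np.abs(spec) ** 2, freqs, loco, freeze)
        if square:
            r = r**2
        values.append(np.log(100.0 * r) if normalize else r)
        start += hop
    return np.asarray(values)
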