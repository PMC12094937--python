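"""Synthetic test-signal generators with known spectral structure.

Two kinds of fixtures are produced: standard-normal white noise, whose flat
spectrum gives every FI definition a closed-form reference value, and
composite locomotion/freeze signals that place narrowband power either in
the locomotion band (walking: a cadence fundamental plus harmonics, all kept
below 3 Hz) or in the freeze band (trembling in place: a 4-7 Hz
oscillation).  A writer emits these as valid Daphnet-format files so the
full file-based pipeline runs without any download.

The generators emulate the spectral *contrast* that the freeze index relies
on, not biomechanically realistic gait: no turns, voluntary stops, gravity
orientation changes, or sensor artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signal_core import Signal

__all__ = [
    "SegmentSpec",
    "generate_white_noise",
    "generate_gait_with_fog",
    "write_daphnet_fixture",
    "make_daphnet_fixture",
]

#: Minimum sampling rate: the 8 Hz freeze-band edge must lie below Nyquist.
MIN_FS = 16.0


def _round_half_up(z: float) -> int:
    return int(np.floor(z + 0.5))


@dataclass(frozen=True)
class SegmentSpec:
    """One segment of a composite gait fixture.

    ``kind`` is ``"stand"`` (noise only), ``"walk"`` (cadence fundamental
    plus two harmonics, all inside the locomotion band), or ``"freeze"``
    (a tremble oscillation inside the freeze band).  The default cadence of
    0.9 Hz keeps the 2nd and 3rd harmonics (1.8, 2.7 Hz) below the 3 Hz band
    edge; the default tremble of 5.0 Hz sits mid freeze band.
    """

    kind: str
    duration: float
    cadence_hz: float = 0.9
    tremble_hz: float = 5.0
    amplitude: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("stand", "walk", "freeze"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.kind == "walk" and not (0.5 <= self.cadence_hz < 3.0):
            raise ValueError(f"walk cadence must lie in [0.5, 3) Hz, got {self.cadence_hz}")
        if self.kind == "freeze" and not (3.0 < self.tremble_hz <= 8.0):
            raise ValueError(f"freeze tremble must lie in (3, 8] Hz, got {self.tremble_hz}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_white_noise(fs: float, duration: float, seed: int) -> Signal:
    """Standard-normal i.i.d. samples — the flat-spectrum benchmark signal."""
    if fs <= MIN_FS:
        raise ValueError(f"fs must exceed {MIN_FS} Hz (freeze band below Nyquist)")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = _round_half_up(fs * duration)
    rng = np.random.default_rng(seed)
    return Signal(samples=rng.standard_normal(n), fs=fs)


def generate_gait_with_fog(
    fs: float,
    segments: list[SegmentSpec],
    seed: int = 0,
) -> tuple[Signal, np.ndarray]:
    """Concatenate stand/walk/freeze segments into one labeled signal.

    Walking segments are the cadence sinusoid plus its 2nd and 3rd harmonics
    at half and a third of the amplitude; freeze segments are a single
    tremble sinusoid; standing is noise only.  Phase is continuous within
    each segment (it restarts across segments).  Returns the signal and a
    per-sample label array with 1 = no freeze (stand/walk) and 2 = freeze.
    """
    if fs <= MIN_FS:
        raise ValueError(f"fs must exceed {MIN_FS} Hz")
    if not segments:
        raise ValueError("at least one segment is required")
    rng = np.random.default_rng(seed)
    pieces, labels = [], []
    for index, seg in enumerate(segments):
        if not isinstance(seg, SegmentSpec):
            raise ValueError(f"segment {index} is not a SegmentSpec")
        n = _round_half_up(seg.duration * fs)
        t = np.arange(n) / fs
        x = rng.standard_normal(n) * seg.noise_sd
        if seg.kind == "walk":
            f0 = seg.cadence_hz
            x = x + seg.amplitude * (
                np.sin(2 * np.pi * f0 * t)
                + 0.5 * np.sin(2 * np.pi * 2 * f0 * t)
                + (1 / 3) * np.sin(2 * np.pi * 3 * f0 * t)
            )
        elif seg.kind == "freeze":
            x = x + seg.amplitude * np.sin(2 * np.pi * seg.tremble_hz * t)
        pieces.append(x)
        labels.append(np.full(n, 2 if seg.kind == "freeze" else 1, dtype=np.int64))
    return Signal(samples=np.concatenate(pieces), fs=fs), np.concatenate(labels)


def write_daphnet_fixture(
    channels: np.ndarray,
    labels: np.ndarray,
    path: str | Path,
    fs: float = 64.0,
) -> np.ndarray:
    """Write a synthetic 9-channel acceleration set as a Daphnet-format file.

    ``channels`` is an (N, 9) float array in mg ordered as shank x/y/z,
    thigh x/y/z, lumbar x/y/z; it is rounded to integers with the same
    floor(z + 0.5) convention the estimators use for sample counts.  Returns
    the (N, 11) integer table that was written, for round-trip checks.
    """
    channels = np.asarray(channels, dtype=float)
    labels = np.asarray(labels)
    if channels.ndim != 2 or channels.shape[1] != 9:
        raise ValueError("channels must be an (N, 9) array")
    if labels.shape != (channels.shape[0],):
        raise ValueError("labels must have one entry per sample")
    if not np.isin(labels, (0, 1, 2)).all():
        raise ValueError("labels must be in {0, 1, 2}")
    n = channels.shape[0]
    time_ms = np.floor(np.arange(n) * 1000.0 / fs + 0.5).astype(np.int64)
    body = np.floor(channels + 0.5).astype(np.int64)
    table = np.column_stack([time_ms, body, labels.astype(np.int64)])
    with Path(path).open("w") as handle:
        for row in table:
            handle.write(" ".join(str(v) for v in row) + "\n")
    return table


def make_daphnet_fixture(
    path: str | Path,
    segments: list[SegmentSpec] | None = None,
    seed: int = 0,
    scale_mg: float = 200.0,
    baseline_mg: float = 1000.0,
) -> tuple[Signal, np.ndarray]:
    """Build a complete synthetic Daphnet file with the gait signal on shank-y.

    The composite locomotion/freeze signal is scaled to mg (``scale_mg`` per
    unit amplitude) around a gravity-like ``baseline_mg`` offset and written
    to the vertical shank channel; the remaining 8 channels carry low-level
    noise around the baseline.  Returns the continuous (pre-rounding) proxy
    signal and the per-sample labels.
    """
    if segments is None:
        segments = [
            SegmentSpec("walk", 30.0),
            SegmentSpec("freeze", 10.0),
            SegmentSpec("walk", 30.0),
        ]
    signal, labels = generate_gait_with_fog(64.0, segments, seed=seed)
    n = len(signal)
    rng = np.random.default_rng(seed + 1)
    channels = baseline_mg + 5.0 * rng.standard_normal((n, 9))
    channels[:, 1] = baseline_mg + scale_mg * signal.samples  # shank vertical axis
    write_daphnet_fixture(channels, labels, path, fs=signal.fs)
    return signal, labels
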