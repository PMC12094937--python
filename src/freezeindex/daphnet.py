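"""Reading Daphnet-format recordings, extracting proxy channels, and FI series I/O.

The Daphnet freezing-of-gait dataset stores each recording as plain text with
11 space-separated integer columns sampled at 64 Hz: a millisecond timestamp,
tri-axial accelerations (in mg) at the ankle (shank), upper leg (thigh), and
trunk (lumbar spine), and an annotation column (0 = outside the experiment,
1 = no freeze, 2 = freeze).  Axis convention per the dataset documentation:
x = horizontal forward, y = vertical, z = horizontal lateral.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .estimators import FISeries
from .signal_core import Signal

__all__ = [
    "DAPHNET_FS",
    "DaphnetRecording",
    "ProxySelector",
    "read_daphnet",
    "extract_proxy",
    "write_fi_csv",
    "read_fi_csv",
    "read_signal_csv",
]

DAPHNET_FS = 64.0
N_COLUMNS = 11

#: Site naming: this package follows the anatomical terms (shank/thigh/lumbar);
#: the dataset documentation calls the same sensors ankle/upper leg/trunk.
SITES = ("shank", "thigh", "lumbar")
CHANNELS = ("x", "y", "z", "magnitude", "sum")
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class DaphnetRecording:
    """One parsed Daphnet recording: per-site (N, 3) acceleration arrays in mg."""

    time_ms: np.ndarray
    shank: np.ndarray
    thigh: np.ndarray
    lumbar: np.ndarray
    annotation: np.ndarray
    fs: float = DAPHNET_FS

    def __len__(self) -> int:
        return self.time_ms.size


@dataclass(frozen=True)
class ProxySelector:
    """Choice of sensor site and channel used as the FI proxy signal.

    ``channel`` is a single axis, the Euclidean magnitude
    sqrt(x^2 + y^2 + z^2), or the plain axis sum x + y + z.
    """

    site: str = "shank"
    channel: str = "y"

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")


def read_daphnet(path: str | Path) -> DaphnetRecording:
    """Parse a Daphnet plain-text recording (11 integer columns, 64 Hz).

    Empty lines are ignored.  A line with the wrong column count or a
    non-integer field raises a ``ValueError`` naming the 1-based line number.
    """
    path = Path(path)
    rows = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != N_COLUMNS:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {N_COLUMNS} columns, found {len(fields)}"
                )
            try:
                rows.append([int(f) for f in fields])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-integer field ({exc})") from None
    if not rows:
        raise ValueError(f"{path.name}: no data lines")
    data = np.asarray(rows, dtype=np.int64)
    annotation = data[:, 10]
    if not np.isin(annotation, (0, 1, 2)).all():
        raise ValueError(f"{path.name}: annotation values must be in {{0, 1, 2}}")
    if np.any(np.diff(data[:, 0]) < 0):
        raise ValueError(f"{path.name}: timestamps must be nondecreasing")
    return DaphnetRecording(
        time_ms=data[:, 0],
        shank=data[:, 1:4].astype(float),
        thigh=data[:, 4:7].astype(float),
        lumbar=data[:, 7:10].astype(float),
        annotation=annotation,
    )


def extract_proxy(recording: DaphnetRecording, selector: ProxySelector | None = None) -> Signal:
    """Extract a single-channel proxy :class:`Signal` from a recording.

    Annotation-0 samples are retained: FI estimation is annotation-agnostic,
    and masking is left to downstream consumers.  Units stay in mg — the FI
    is scale-invariant.
    """
    if selector is None:
        selector = ProxySelector()
    xyz = getattr(recording, selector.site)
    if selector.channel in _AXIS_INDEX:
        samples = xyz[:, _AXIS_INDEX[selector.channel]]
    elif selector.channel == "magnitude":
        samples = np.sqrt(np.sum(xyz**2, axis=1))
    else:  # sum
        samples = np.sum(xyz, axis=1)
    return Signal(samples=samples, fs=recording.fs, t0=recording.time_ms[0] / 1000.0)


def write_fi_csv(series: FISeries, path: str | Path) -> None:
    """Write an FI series as a two-column CSV with a config header comment.

    Floats are written with 17 significant digits so a read-back reproduces
    them exactly; NaN windows serialize as ``nan``.
    """
    path = Path(path)
    import json as _json

    lines = [
        f"# method={series.method}",
        f"# config={_json.dumps(series.config, sort_keys=True)}",
        f"# config_hash={series.config_hash()}",
        "time_s,fi",
    ]
    for t, v in zip(series.times, series.values):
        lines.append(f"{t:.17g},{v:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_fi_csv(path: str | Path) -> FISeries:
    """Read an FI series written by :func:`write_fi_csv`."""
    import json as _json

    path = Path(path)
    method = "unknown"
    config: dict = {}
    times, values = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if body.startswith("method="):
                method = body.removeprefix("method=")
            elif body.startswith("config="):
                config = _json.loads(body.removeprefix("config="))
            continue
        if line.startswith("time_s"):
            continue
        t_str, v_str = line.split(",")
        times.append(float(t_str))
        values.append(float(v_str))
    return FISeries(times=np.asarray(times), values=np.asarray(values), method=method, config=config)


def read_signal_csv(path: str | Path) -> Signal:
    """Read a generic two-column (time_s, value) CSV as a :class:`Signal`.

    The sampling frequency is inferred from the time column, which must be
    uniform to within 1 part in 10^6 of the sample interval.
    """
    import pandas as pd

    frame = pd.read_csv(path, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, value)")
    t = frame.iloc[:, 0].to_numpy(dtype=float)
    v = frame.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    if not np.allclose(dt, dt.mean(), rtol=1e-6, atol=0):
        raise ValueError(f"{path}: time column must be uniformly sampled")
    return Signal(samples=v, fs=1.0 / dt.mean(), t0=t[0])
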