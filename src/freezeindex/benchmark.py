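"""White-noise performance benchmark and hyperparameter sweeps for FI estimators.

Gaussian white noise has a flat power spectrum, so every FI definition has a
closed-form reference value on it and an ideal estimator would return that
constant at all times.  The benchmark measures how far each estimator strays:
the per-trial standard deviation of the FI series (variability) and its RMSE
from the closed-form value (accuracy), averaged over M independent noise
realizations shared across methods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .estimators import (
    LEGACY_SPECS,
    METHOD_ORDER,
    FISeries,
    MultitaperConfig,
    estimate_fi_legacy,
    estimate_fi_multitaper,
    theoretical_white_noise_fi,
)
from .signal_core import Signal
from .synthetic import generate_white_noise

__all__ = ["derive_trial_seed", "run_white_noise_benchmark", "format_benchmark_table", "sweep_hyperparameters"]

logger = logging.getLogger(__name__)

#: Map between the conventional sweep parameter symbols and config fields.
SWEEP_PARAMS = {
    "T": "window",
    "L": "n_tapers",
    "B": "half_bandwidth",
    "f_t": "f_threshold",
    "window": "window",
    "n_tapers": "n_tapers",
    "half_bandwidth": "half_bandwidth",
    "f_threshold": "f_threshold",
}


def derive_trial_seed(seed: int, fs: float, trial: int) -> int:
    """Deterministic per-(fs, trial) seed from one base seed (counter scheme)."""
    return (int(seed) * 100_003 + int(round(fs)) * 131 + int(trial)) % (2**31)


def _estimate(method: str, signal: Signal) -> FISeries:
    if method == "multitaper":
        # MAF deliberately off: smoothing would mask the estimator's own variance.
        return estimate_fi_multitaper(signal, MultitaperConfig(maf_width=0.0))
    return estimate_fi_legacy(signal, LEGACY_SPECS[method])


def run_white_noise_benchmark(
    methods: list[str] | None = None,
    fs_list: tuple[float, ...] = (64.0, 100.0, 256.0),
    n_trials: int = 10,
    duration: float = 300.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate FI estimators on shared standard-normal white-noise signals.

    For each sampling frequency, ``n_trials`` independent standard-normal
    signals of ``duration`` seconds are generated; every method consumes the
    identical realizations.  Per trial the FI series' standard deviation and
    its RMSE from the method's closed-form flat-spectrum value are computed
    (NaN windows excluded); the table reports their mean and standard
    deviation over trials.

    Returns a DataFrame with one row per (method, fs) and columns
    ``std_mean, std_sd, rmse_mean, rmse_sd, n_trials, duration, seeds``.
    """
    if methods is None:
        methods = list(METHOD_ORDER)
    unknown = [m for m in methods if m != "multitaper" and m not in LEGACY_SPECS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    longest = max(
        MultitaperConfig().window if m == "multitaper" else LEGACY_SPECS[m].window
        for m in methods
    )
    if duration < longest:
        raise ValueError(
            f"duration {duration} s is shorter than the longest method window {longest} s"
        )

    rows = []
    for fs in fs_list:
        trial_seeds = [derive_trial_seed(seed, fs, m) for m in range(n_trials)]
        signals = [generate_white_noise(fs, duration, s) for s in trial_seeds]
        for method in methods:
            theory = theoretical_white_noise_fi(method)
            stds = np.empty(n_trials)
            rmses = np.empty(n_trials)
            for i, sig in enumerate(signals):
                values = _estimate(method, sig).values
                stds[i] = np.nanstd(values)
                rmses[i] = np.sqrt(np.nanmean((values - theory) ** 2))
            rows.append(
                {
                    "method": method,
                    "fs": fs,
                    "std_mean": stds.mean(),
                    "std_sd": stds.std(ddof=1),
                    "rmse_mean": rmses.mean(),
                    "rmse_sd": rmses.std(ddof=1),
                    "theory": theory,
                    "n_trials": n_trials,
                    "duration": duration,
                    "seeds": ";".join(str(s) for s in trial_seeds),
                }
            )
    return pd.DataFrame(rows)


def format_benchmark_table(table: pd.DataFrame) -> str:
    """Render the benchmark as a plain-text method x sampling-frequency table."""
    lines = [f"{'fs [Hz]':>8}  {'method':<12} {'STD':>14} {'RMSE':>14}"]
    for fs, group in table.groupby("fs", sort=True):
        for _, row in group.iterrows():
            lines.append(
                f"{fs:>8g}  {row['method']:<12}"
                f" {row['std_mean']:.2f} ± {row['std_sd']:.2f}   "
                f" {row['rmse_mean']:.2f} ± {row['rmse_sd']:.2f}"
            )
    return "\n".join(lines)


def sweep_hyperparameters(
    signal: Signal,
    param: str,
    values: list,
    base: MultitaperConfig | None = None,
) -> list[tuple[float, FISeries]]:
    """Compute raw (non-standardized) multitaper FI series over a parameter sweep.

    ``param`` is one of the multitaper hyperparameters (window length T,
    taper count L, half-bandwidth B, or threshold frequency f_t); all other
    parameters are held at ``base``.  Values that violate the joint taper
    constraint L <= floor(2B) - 1 (or any other config invariant) are skipped
    with a warning.  Returns ``[(value, series), ...]`` for the valid values.
    """
    if param not in SWEEP_PARAMS:
        raise ValueError(f"unknown sweep parameter {param!r}; expected one of {sorted(set(SWEEP_PARAMS))}")
    field = SWEEP_PARAMS[param]
    if base is None:
        base = MultitaperConfig()
    results: list[tuple[float, FISeries]] = []
    for value in values:
        try:
            config = replace(base, **{field: value})
        except ValueError as exc:
            warnings.warn(f"skipping {param}={value}: {exc}", stacklevel=2)
            continue
        results.append((value, estimate_fi_multitaper(signal, config)))
    if not results:
        raise ValueError(f"no valid configurations in sweep of {param} over {values}")
    return results
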