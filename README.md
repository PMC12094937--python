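# freezeindex

Standardized freeze-index estimation for freezing-of-gait monitoring.

Freezing of gait (FOG) — the episodic inability to step forward despite the
intention to do so — affects a majority of people with advanced Parkinson's
disease. The **freeze index (FI)** is the classic interpretable biomarker
for it: during a freeze the dominant energy of a body-worn accelerometer
shifts from the stepping band into a higher "trembling" band, and the FI
tracks that shift as the log-scaled band-power ratio over a sliding window
of length T:

```
FI(t) = ln( 100 · ∫_[f_t, 8 Hz] PSD(f) df / ∫_[0.5, f_t] PSD(f) df )
```

with threshold frequency f_t = 3 Hz by default. Historical implementations
of this idea disagree on nearly every detail — window length, hop, bands,
preprocessing, spectral estimator, normalization — which makes their outputs
incomparable. This package provides, for researchers and medical-device
engineers working on digital gait biomarkers:

- a **standardized multitaper FI estimator**: per window, linear detrend →
  Slepian (DPSS) multitaper PSD (L = 4 tapers, half-bandwidth B = 2.5) with
  4× zero-padding → trapezoidal band integration → ln(100·ratio) → optional
  moving average;
- faithful re-implementations of the **four historical definitions**
  (Moore 2008, Bachlin 2009, Zach 2015, Cockx 2023) as data-driven
  `MethodSpec`s;
- a **white-noise benchmark**: on Gaussian noise every definition has a
  closed-form value (ln(200) ≈ 5.30 for the standard one), so estimator
  variability (STD) and accuracy (RMSE) are measurable exactly;
- **similarity analysis**: pairwise MAD / Pearson ρ / R² between resampled,
  standardized FI series, plus a leave-one-out range-IOU that flags outlier
  definitions;
- a reader for the public **Daphnet** FOG dataset format, synthetic
  locomotion/freeze signal generators, and a `freezeindex` CLI with run
  manifests.

## Worked example

```python
import numpy as np
from freezeindex import (SegmentSpec, generate_gait_with_fog,
                         estimate_fi_multitaper, theoretical_white_noise_fi)

# 30 s walking, 10 s freeze (5 Hz tremble), 30 s walking, at 64 Hz
sig, labels = generate_gait_with_fog(
    64.0,
    [SegmentSpec("walk", 30.0), SegmentSpec("freeze", 10.0), SegmentSpec("walk", 30.0)],
    seed=0,
)
series = estimate_fi_multitaper(sig)            # T=5 s, L=4, B=2.5, f_t=3 Hz

centers = np.floor(series.times * 64.0 + 0.5).astype(int)
print(f"median FI while walking : {np.median(series.values[labels[centers] == 1]):.2f}")
print(f"median FI while frozen  : {np.median(series.values[labels[centers] == 2]):.2f}")
print(f"flat-spectrum reference : {theoretical_white_noise_fi('multitaper'):.2f}")
```

prints

```
median FI while walking : 0.54
median FI while frozen  : 10.28
flat-spectrum reference : 5.30
```

Walking keeps nearly all power below 3 Hz (FI far below the flat-spectrum
reference of ln(200) ≈ 5.30); the 5 Hz tremble pushes the FI far above it.
The absolute level matters less than the relative change — the package
deliberately makes no FOG/no-FOG classification decisions.

The same computation from the shell, on a Daphnet-format file:

```sh
freezeindex compute S02R01.txt --method multitaper --site shank --channel y \
    --output fi.csv
freezeindex benchmark --fs 64,100,256 --trials 10 --duration 300 --seed 1 \
    --output table.csv
freezeindex compare S02R01.txt --methods all --output similarity.json
```

Every command writes a `.manifest.json` with the resolved configuration,
seeds, input checksums, and package version.

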