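# ppgfilt

Filter benchmarking for short photoplethysmogram (PPG) records using the
skewness signal-quality index.

## The problem

A PPG is the optical pulse waveform a wearable or clinical probe records
from peripheral tissue — one asymmetric pulse per heartbeat, with a sharp
systolic upstroke followed by a smaller dicrotic (diastolic) wave.  Raw PPG
is easily contaminated by baseline wander (respiration, vasomotion), mains
interference, muscle tremor, broadband sensor noise, and motion artifacts,
so every PPG pipeline starts with a filter — and the choice of filter
family and order materially changes how usable the waveform is.

`ppgfilt` is for researchers and device engineers who need to choose that
filter systematically.  It scores signal quality with the skewness index,
applies a nine-family bank of digital filters zero-phase, and ranks all 90
family × order configurations by how much they improve quality on a graded
dataset.  A synthetic generator produces labeled 2.1-s, 1-kHz, 12-bit
records (graded G1 excellent / G2 acceptable / G3 unfit) so the whole
pipeline runs without any data download.

## The statistic and the bank

Signal quality of a window of N samples x_1..x_N is its skewness — the
third standardized moment with population normalization:

    S = (1/N) * Σ_i [ (x_i − μ̂) / σ ]³

Clean pulse waves are strongly asymmetric (high positive S); symmetric
noise scores near 0.  A record is scored on consecutive non-overlapping
1-s windows; the record SQI is the maximum over windows.

The bank holds 9 families × 10 orders = 90 configurations:

| family | order grid | notes |
|---|---|---|
| moving average, median | 0.05–0.50 s window | centered, window forced odd |
| FIR (Hamming, least-squares) | 0.05–0.50 s length | bandpass, linear phase |
| Butterworth, Chebyshev I/II, elliptic | design order 2–20 | bandpass SOS cascades |
| wavelet (db2, stationary transform) | level 1–10 | soft universal threshold |

Design constants: Chebyshev I / elliptic passband ripple 0.1 dB; Chebyshev
II stopband 20 dB; elliptic stopband 30 dB.  Default passband 0.5–8 Hz.
"Order" for the IIR families is the design-function argument, so a
"4th-order" bandpass has effective order 8.  Linear filters are applied
forward-backward (`filtfilt`) for zero phase distortion.

The recommended configuration — the one that most improves the skewness
SQI across quality grades — is the **design-order-4 Chebyshev type II
bandpass**, available directly as `optimal_filter(fs, band)`.

## Worked example

```python
from ppgfilt import apply_zero_phase, optimal_filter, windowed_sqi
from ppgfilt.synth import generate_record

f = optimal_filter(1000.0)              # cheby2, design order 4, 0.5-8 Hz
rec = generate_record("G2", seed=11)    # acceptable-grade synthetic record
before = windowed_sqi(rec).record_sqi
after = windowed_sqi(apply_zero_phase(f, rec)).record_sqi
print(f"raw {before:+.3f} -> filtered {after:+.3f}")
```

prints

```
raw +0.452 -> filtered +0.768
```

the skewness SQI of this noisy record rises from 0.45 to 0.77 because the
filter removes the wander and high-frequency noise that were masking the
pulse asymmetry.  Running the reduced benchmark in
`examples/03_run_benchmark.py` (Chebyshev II + Butterworth families, 10
records per grade, seed 1) prints

```
rank  family        order  combined score
   1  cheby2           4  1.917
   2  cheby2           6  1.915
   3  cheby2           2  1.880
```

where the combined score of a configuration sums its per-group min-max
normalized mean SQIs (range 0–3).  See `examples/` for scoring, filtering,
benchmarking, and dataset I/O walk-throughs, and the CLI:

```bash
ppgfilt simulate --out data/ --n 36 --n 132 --n 51 --seed 7
ppgfilt benchmark data/manifest.csv --out report.csv
```

## Layout

- `src/ppgfilt/` — library (`records`, `io`, `sqi`, `filters`, `benchmark`,
  `synth`, `config`, `cli`)
- `examples/` — narrative example scripts, one per capability
- `docs/methods.md` — models, parameters, numerical choices, limitations
- `tests/` — pytest suite (unit, property, and acceptance tests)
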