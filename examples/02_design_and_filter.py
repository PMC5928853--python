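"""Design the recommended filter and apply it zero-phase to a noisy record.

The recommended configuration is the design-order-4 Chebyshev type II
bandpass (0.5-8 Hz, 20 dB stopband), applied forward-backward so waveform
landmarks are not shifted in time.  The example prints the record SQI
before and after filtering an acceptable-grade (G2) record.
"""

from ppgfilt import apply_zero_phase, optimal_filter, windowed_sqi
from ppgfilt.synth import generate_record

fs = 1000.0
f = optimal_filter(fs)
print(f"filter: {f.spec.family}, design order {f.spec.order_param} "
      f"(effective order {f.effective_order}), "
      f"band {f.band.f_low}-{f.band.f_high} Hz, "
      f"stopband {f.spec.atten_db} dB, {len(f.sos)} second-order sections")

rec = generate_record("G2", seed=11)
before = windowed_sqi(rec).record_sqi
after = windowed_sqi(apply_zero_phase(f, rec)).record_sqi
print(f"G2 record SQI: raw {before:+.3f} -> filtered {after:+.3f}")
print("The rise in skewness reflects restored pulse-wave asymmetry after "
      "removing baseline wander and high-frequency noise.")
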