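"""From raw traces to frontal alpha asymmetry.

Pipeline: common-average reference -> drop the first 2 s of rest -> Welch
spectra (2-s Hann windows, 0.5-s step, windows overlapping rejected segments
discarded) -> mean 8-13 Hz log power -> right-minus-left difference per
homologous frontal pair.  Negative FAA = relatively more left alpha power,
the pattern classically associated with depression.
"""

import numpy as np

from faaverse import (
    apply_average_reference,
    band_log_power,
    crop_rest,
    pair_asymmetry,
    welch_psd,
    welch_t,
    generate_study,
)
from faaverse.synth import StudyConfig

cfg = StudyConfig(study_id="demo", n_per_group={"diagnosed": 25, "healthy": 25},
                  sfreq=125.0, duration=62.0, asymmetry_effect_d=-1.0, seed=7)
raw = crop_rest(apply_average_reference(generate_study(cfg)), 2)
spec = welch_psd(raw)

mean_psd = spec.power.mean(axis=(0, 1))
peak = spec.freqs[np.argmax(mean_psd[spec.freqs >= 2] ) + int((spec.freqs < 2).sum())]
print(f"Grand-average PSD peak: {peak:g} Hz (alpha rest rhythm)")

asym = pair_asymmetry(band_log_power(spec))
diag = (raw.meta["group"] == "diagnosed").to_numpy()
print("\nMean FAA (log right - log left) by pair and group:")
for k, (left, right) in enumerate(asym.pairs):
    m_d = asym.values[diag, k].mean()
    m_h = asym.values[~diag, k].mean()
    print(f"  {left}-{right}:  diagnosed {m_d:+.3f}   healthy {m_h:+.3f}")

k = asym.pair_index("F3-F4")
res = welch_t(asym.values[diag, k], asym.values[~diag, k])
print(f"\nF3-F4 DvsHC Welch t = {res.statistic:.3f}, p = {res.p:.4f}, "
      f"Cohen's d = {res.effect_size:.3f}")
print("A negative t / d means lower FAA in the diagnosed group — the "
      "injected left-sided asymmetry is recovered.")
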