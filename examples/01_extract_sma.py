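"""Separate scalp muscle activity from EEG rhythms on one synthetic channel.

Builds a 3-channel mixture of narrowband rhythms (8, 11 Hz) and broadband
EMG-like noise (40-150 Hz), runs the SSA + autocorrelation split, and
scores the extraction against the generator's ground truth.
"""

import numpy as np
from scipy.signal import welch

from smanet import extract_sma
from smanet.synthetic import SynthSpec, generate_recording

spec = SynthSpec(
    channels=("Fp1", "Fp2", "Fz"),
    duration_s=20.0,
    seed=3,
    rhythms=((8.0, 30.0), (11.0, 20.0)),
    emg_band=(40.0, 150.0),
    emg_rms=25.0,
    kappa=0.5,
)
rec, truth = generate_recording(spec)
result = extract_sma(rec, threshold=0.8)

print("components sent to SMA per channel:",
      [s.n_sma for s in result.stats], "of 30")
for i, ch in enumerate(result.channels):
    r = np.corrcoef(result.sma[i], truth.emg[i])[0, 1]
    print(f"{ch}: corr(extracted SMA, true EMG part) = {r:.3f}")

f, p_sma = welch(result.sma[0], fs=rec.fs, nperseg=2048)
f, p_eeg = welch(result.retained_eeg[0], fs=rec.fs, nperseg=2048)
print(f"SMA power above 50 Hz:      {p_sma[f > 50].sum() / p_sma.sum():.1%}")
print(f"retained EEG power below 50 Hz: {p_eeg[f < 50].sum() / p_eeg.sum():.1%}")

# Correlations near 1 mean the autocorrelation threshold cleanly assigned
# the broadband components to SMA; the power fractions confirm the split
# matches the EMG-above-50-Hz / EEG-below-50-Hz picture.
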