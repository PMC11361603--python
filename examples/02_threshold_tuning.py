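"""Select the autocorrelation threshold from interictal control segments.

Sweeps thresholds 0.50-0.95 over three 62 s controls whose broadband
components sit at R ~ 0.5-0.8 and rhythms above 0.9, and reports the
coherence separation that drives the choice.
"""

import warnings

from smanet import tune_threshold
from smanet.synthetic import SynthSpec, generate_recording

controls = []
for seed in (11, 12, 13):
    spec = SynthSpec(
        channels=("Fp1", "Fp2", "Fz"),
        duration_s=62.0,
        state="interictal",
        seed=seed,
        rhythms=((6.0, 25.0), (10.0, 25.0), (21.0, 15.0), (27.0, 15.0)),
        emg_band=(55.0, 85.0),
        emg_rms=15.0,
        kappa=0.3,
    )
    controls.append(generate_recording(spec)[0])

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    curve = tune_threshold(controls)

print("thr   WPC(1-30)  WPC(31-100)  separation  ln P50-70 ratio")
for t, lo, hi, pr in zip(curve.thresholds, curve.wpc_low_band,
                         curve.wpc_high_band, curve.power_ratio_log):
    print(f"{t:.2f}  {lo:9.3f}  {hi:11.3f}  {hi - lo:+10.3f}  {pr:+8.2f}")
print(f"selected threshold: {curve.selected}")

# The separation column peaks where the extracted signal coheres with the
# raw frontal electrode at EMG frequencies (31-100 Hz) but not at EEG
# frequencies (1-30 Hz): everything muscle-like captured, no rhythm leakage.
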