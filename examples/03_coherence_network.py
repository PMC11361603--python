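"""Build the wavelet-phase-coherence network of extracted SMA.

Generates a full 19-electrode ictal recording, extracts SMA, computes all
361 pairwise coherence matrices, and walks the averaging chain down to the
two per-seizure numbers the risk model consumes.
"""

import numpy as np

from smanet import extract_sma, pairwise_wpc, summarize_wpc, wavelet_phase
from smanet.synthetic import SynthSpec, generate_recording

rec, _ = generate_recording(SynthSpec(duration_s=26.0, kappa=0.6, seed=42))
ext = extract_sma(rec, threshold=0.8)

freqs = np.arange(1.0, 31.0)
phases = [(ch, wavelet_phase(ext.sma[i], rec.fs, freqs))
          for i, ch in enumerate(ext.channels)]
wset = pairwise_wpc(phases, window_s=1.0)
print(f"pair matrices: {wset.n_pairs} "
      f"({len(ext.channels)} x {len(ext.channels)} electrodes)")

summary = summarize_wpc(wset, rec.ictal_epochs()[0])
for band in summary.bands:
    per_el = summary.per_electrode[band]
    print(f"band {band[0]:g}-{band[1]:g} Hz: per-seizure WPC = "
          f"{summary.per_seizure[band]:.3f} "
          f"(electrode range {per_el.min():.3f}-{per_el.max():.3f}, "
          f"18 partners each)")

# With kappa = 0.6, sixty percent of each channel's muscle drive is shared,
# and the per-seizure coherence sits well above the independent-noise null.
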