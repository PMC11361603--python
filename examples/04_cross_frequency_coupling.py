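"""n:m phase-phase coupling between slow and fast activity.

Constructs a signal whose 13 Hz phase exactly drives a 65 Hz tone (5:1)
plus noise, and locates the coupling peak on the (f_slow, f_fast) map.
"""

import numpy as np

from smanet import ppc_map, wavelet_phase

fs = 512.0
rng = np.random.default_rng(5)
t = np.arange(60_000) / fs
phi = 2 * np.pi * 13 * t

slow_signal = np.cos(phi) + 0.3 * rng.standard_normal(t.size)
fast_signal = np.cos(phi) + np.cos(5 * phi) + 0.3 * rng.standard_normal(t.size)

p_slow = wavelet_phase(slow_signal, fs, np.arange(1.0, 31.0))
p_fast = wavelet_phase(fast_signal, fs, np.arange(1.0, 101.0))
pm = ppc_map(p_slow, p_fast)

f1, f2, val = pm.peak()
i = np.argmin(np.abs(pm.f_slow - f1))
j = np.argmin(np.abs(pm.f_fast - f2))
print(f"coupling peak at ({f1:g} Hz, {f2:g} Hz), "
      f"PPC = {val:.3f}, ratio n:m = {pm.n[i, j]}:{pm.m[i, j]}")
print(f"map median away from peak: {np.nanmedian(pm.values):.3f}")

# The peak lands at the driven pair (13, 65) with the 5:1 ratio and PPC
# near 1; elsewhere the map stays near the Rayleigh null.
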