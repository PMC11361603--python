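"""Synthetic multichannel recordings with EEG-like and EMG-like structure.

Each channel is a sum of narrowband rhythms and a broadband EMG-like
source.  Rhythms are narrowband stochastic oscillators (band-limited noise
of ~1.5 Hz bandwidth around each rhythm frequency, independent per channel)
rather than pure tones: a pure tone at the same frequency on two channels
is *always* perfectly phase-coherent - a constant phase offset does not
decohere a resultant - whereas independent narrowband processes decohere
over ~1/bandwidth, so retained-EEG coherence is non-trivial.  Their lag-1
autocorrelation remains near cos(2*pi*f/fs) ~ 1.  The EMG-like source is
band-passed white noise with dominant power above 50 Hz and lag-1
autocorrelation well below the rhythms'.  A mixing weight ``kappa`` blends a single shared broadband
drive into every channel against channel-private noise:

    emg_ch = kappa * shared + sqrt(1 - kappa^2) * private_ch

so ``kappa`` directly controls the inter-channel phase coherence of the
muscle-like part - the quantity the downstream network analysis measures.
Cohorts of two groups differing only in ``kappa`` therefore have a built-in,
known effect for the classifier to find.

The generator returns the ground-truth rhythm/EMG parts alongside the
mixture, so extraction quality can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import TEN_TWENTY_19, Epoch, Recording, RecordingMeta

__all__ = ["SynthSpec", "GroundTruth", "generate_recording", "generate_cohort"]

#: Default per-tone peak amplitudes (uV): ictal rhythms are modest against a
#: prominent muscle signal (rhythm:EMG RMS about 1:2); interictally the
#: rhythms dominate (about 2:1).
ICTAL_RHYTHM_RMS = 20.0
ICTAL_EMG_RMS = 40.0
INTERICTAL_RHYTHM_RMS = 30.0
INTERICTAL_EMG_RMS = 15.0

#: Rhythm frequencies (Hz): delta/theta/alpha plus beta tones so that the
#: narrowband part spans both summary bands and the upper beta range.
DEFAULT_RHYTHM_FREQS = (3.0, 8.0, 11.0, 21.0, 27.0)


def _rhythm_amplitudes(freqs: tuple[float, ...], total_rms: float) -> tuple:
    # equal-power tones; peak amplitude a with RMS a/sqrt(2) per tone
    per_tone_rms = total_rms / np.sqrt(len(freqs))
    return tuple((f, float(per_tone_rms * np.sqrt(2.0))) for f in freqs)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic recording.

    ``rhythms`` is a tuple of ``(frequency_hz, peak_amplitude_uv)``;
    ``rhythm_bandwidth`` the spectral width of each rhythm (0 gives a pure
    tone with a random per-channel phase); ``emg_band`` the broadband
    source's passband; ``kappa`` in [0, 1] the shared-drive mixing weight;
    ``cfc`` an optional ``(f_slow, ratio)`` adding an exactly ratio:1
    phase-coupled tone pair.
    """

    channels: tuple[str, ...] = TEN_TWENTY_19
    fs: float = 512.0
    duration_s: float = 26.0
    state: str = "ictal"  # sets default amplitudes and the epoch label
    rhythms: tuple[tuple[float, float], ...] | None = None
    rhythm_bandwidth: float = 1.5
    emg_band: tuple[float, float] = (40.0, 150.0)
    emg_rms: float | None = None
    kappa: float = 0.5
    cfc: tuple[float, int] | None = None
    cfc_amplitude: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa={self.kappa} outside [0, 1]")
        if self.state not in ("ictal", "interictal"):
            raise ValueError(f"state must be ictal/interictal, got {self.state!r}")
        lo, hi = self.emg_band
        if not (0.0 < lo < hi):
            raise ValueError(f"invalid EMG band {self.emg_band}")
        if lo >= self.fs / 2:
            raise ValueError(f"EMG band {self.emg_band} entirely above Nyquist")

    def resolved_rhythms(self) -> tuple[tuple[float, float], ...]:
        if self.rhythms is not None:
            return self.rhythms
        total = ICTAL_RHYTHM_RMS if self.state == "ictal" else INTERICTAL_RHYTHM_RMS
        return _rhythm_amplitudes(DEFAULT_RHYTHM_FREQS, total)

    def resolved_emg_rms(self) -> float:
        if self.emg_rms is not None:
            return self.emg_rms
        return ICTAL_EMG_RMS if self.state == "ictal" else INTERICTAL_EMG_RMS


@dataclass
class GroundTruth:
    """Per-channel constituent parts of a generated recording."""

    rhythm: np.ndarray  # (n_channels, n_samples)
    emg: np.ndarray
    cfc: np.ndarray | None = None


def _bandpassed_noise(rng, n, fs, band) -> np.ndarray:
    """Unit-RMS band-passed white noise (gentle 2nd-order Butterworth skirts).

    The shallow skirts deliberately leave a small low-frequency tail, like
    real surface EMG whose spectrum extends below its dominant band.
    """
    hi = min(band[1], 0.95 * fs / 2)
    sos = signal.butter(2, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def generate_recording(spec: SynthSpec) -> tuple[Recording, GroundTruth]:
    """Generate one recording plus its ground-truth parts, reproducibly.

    Each channel is ``rhythms + emg (+ cfc)`` where the EMG part mixes the
    shared and private broadband sources with weight ``spec.kappa``.  The
    epoch annotation covers the record interior (1 s margins) with the
    spec's state label.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    n_ch = len(spec.channels)

    rhythms = spec.resolved_rhythms()
    rhythm_part = np.zeros((n_ch, n))
    bw = spec.rhythm_bandwidth
    for ci in range(n_ch):
        for f, amp in rhythms:
            if bw > 0:
                lo = max(f - bw / 2, 0.25)
                osc = _bandpassed_noise(rng, n, spec.fs, (lo, f + bw / 2))
                rhythm_part[ci] += (amp / np.sqrt(2.0)) * osc
            else:
                rhythm_part[ci] += amp * np.cos(
                    2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
                )

    emg_rms = spec.resolved_emg_rms()
    shared = _bandpassed_noise(rng, n, spec.fs, spec.emg_band)
    emg_part = np.zeros((n_ch, n))
    k = spec.kappa
    for ci in range(n_ch):
        private = _bandpassed_noise(rng, n, spec.fs, spec.emg_band)
        emg_part[ci] = emg_rms * (k * shared + np.sqrt(1.0 - k * k) * private)

    cfc_part = None
    data = rhythm_part + emg_part
    if spec.cfc is not None:
        f_slow, ratio = spec.cfc
        cfc_part = np.zeros((n_ch, n))
        for ci in range(n_ch):
            phi = 2 * np.pi * f_slow * t + rng.uniform(0, 2 * np.pi)
            cfc_part[ci] = spec.cfc_amplitude * (np.cos(phi) + np.cos(ratio * phi))
        data = data + cfc_part

    margin = min(1.0, spec.duration_s / 4)
    epoch = (
        Epoch("ictal", margin, spec.duration_s - margin)
        if spec.state == "ictal"
        else Epoch("interictal", 0.0, spec.duration_s)
    )
    rec = Recording(
        channels=list(spec.channels),
        fs=spec.fs,
        data=data,
        epochs=[epoch],
        meta=RecordingMeta(),
    )
    return rec, GroundTruth(rhythm_part, emg_part, cfc_part)


def generate_cohort(
    n_group_a: int = 4,
    n_group_b: int = 4,
    kappa_a: float = 0.8,
    kappa_b: float = 0.2,
    seizures_per_subject: int = 3,
    seed: int = 0,
    base_spec: SynthSpec | None = None,
    group_labels: tuple[str, str] = ("SUDEP", "non-SUDEP"),
) -> list[tuple[Recording, GroundTruth]]:
    """Two labelled cohorts differing only in the shared-drive weight kappa.

    ``n_group_a`` subjects with ``seizures_per_subject`` recordings each use
    ``kappa_a`` (labelled ``group_labels[0]``), and likewise for group B.
    Per-recording seeds are derived deterministically from the master seed,
    so the same seed reproduces the cohort exactly.
    """
    base = base_spec if base_spec is not None else SynthSpec()
    ss = np.random.SeedSequence(seed)
    children = iter(ss.generate_state(2 * (n_group_a + n_group_b) * seizures_per_subject))

    out: list[tuple[Recording, GroundTruth]] = []
    for gi, (n_subj, kappa, label) in enumerate(
        [(n_group_a, kappa_a, group_labels[0]), (n_group_b, kappa_b, group_labels[1])]
    ):
        prefix = "AB"[gi]
        for subj in range(n_subj):
            for sz in range(seizures_per_subject):
                child_seed = int(next(children)) % (2**31)
                spec = replace(base, kappa=kappa, seed=child_seed)
                rec, truth = generate_recording(spec)
                rec.meta = RecordingMeta(
                    patient_id=f"{prefix}{subj + 1:02d}",
                    seizure_id=f"{prefix}{subj + 1:02d}-s{sz + 1}",
                    group=label,
                )
                out.append((rec, truth))
    return out
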