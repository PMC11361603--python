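"""Wavelet phase extraction, phase coherence networks and n:m coupling.

Instantaneous phase is taken from a complex Morlet continuous wavelet
transform (centre frequency parameter omega0 = 6) on a 1 Hz grid.  The
wavelet phase coherence (WPC) of two channels at frequency f is the modulus
of the time-averaged unit phasor of their phase difference,

    WPC(f) = | mean_t exp(i (phi1(f, t) - phi2(f, t))) |  in [0, 1],

computed in sliding windows and then averaged over the ictal interval.
n:m phase-phase coupling (PPC) generalises this across frequencies:
| mean_t exp(i (n theta1(t) - m theta2(t))) |, equal to 1 under exact n:m
locking and near T^{-1/2} for independent phases (Rayleigh null).

Samples inside the wavelet cone of influence at the record edges are
excluded from every average rather than zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pywt

from .io import TEN_TWENTY_19, EDGE_TRANSIENT_S, Epoch, canonical_label

__all__ = [
    "TimeFreqPhase",
    "WPCSet",
    "WPCSummary",
    "PPCMap",
    "wavelet_phase",
    "wpc",
    "pairwise_wpc",
    "ppc",
    "ppc_map",
    "summarize_wpc",
]

#: Morlet centre-frequency parameter omega0; the pywt ``cmor`` equivalent has
#: bandwidth B = 2 and centre frequency C = omega0 / (2 pi).
OMEGA0 = 6.0
_CMOR_B = 2.0
_CMOR_C = OMEGA0 / (2.0 * np.pi)

DEFAULT_FREQS = np.arange(1.0, 101.0)

LOW_BAND = (1.0, 12.0)
HIGH_BAND = (13.0, 30.0)
DEFAULT_BANDS = (LOW_BAND, HIGH_BAND)


@dataclass
class TimeFreqPhase:
    """Instantaneous phase per analysis frequency with an edge-validity mask."""

    freqs: np.ndarray
    phases: np.ndarray       # (n_freqs, n_samples), radians in (-pi, pi]
    valid_mask: np.ndarray   # (n_freqs, n_samples) bool
    fs: float

    @property
    def n_samples(self) -> int:
        return self.phases.shape[1]

    @property
    def T(self) -> np.ndarray:
        """Valid sample count per frequency."""
        return self.valid_mask.sum(axis=1)


def wavelet_phase(
    s: np.ndarray, fs: float, freqs: np.ndarray | None = None
) -> TimeFreqPhase:
    """Instantaneous phase of ``s`` at each grid frequency via complex Morlet CWT.

    The validity mask excludes, at every frequency, the cone of influence at
    both record edges (two Gaussian widths of the wavelet, about two cycles)
    and any sample where the transform is exactly zero (no phase defined).
    Frequencies with fewer than three cycles in the record are fully masked
    with a warning.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1:
        raise ValueError("expected a 1-D series")
    freqs = DEFAULT_FREQS.copy() if freqs is None else np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("analysis frequencies must lie in (0, fs/2)")

    scales = _CMOR_C * fs / freqs
    wavelet = pywt.ContinuousWavelet(f"cmor{_CMOR_B}-{_CMOR_C}")
    coef, _ = pywt.cwt(s, scales, wavelet, method="fft")

    phases = np.angle(coef)
    phases[phases <= -np.pi] = np.pi  # contract: phase in (-pi, pi]
    valid = np.abs(coef) > 0.0

    N = s.size
    too_short = 3.0 * fs / freqs > N
    if np.any(too_short):
        warnings.warn(
            f"frequencies {freqs[too_short]} Hz have fewer than 3 cycles in "
            f"{N / fs:.2f} s; their rows are fully masked"
        )
    for i, a in enumerate(scales):
        if too_short[i]:
            valid[i] = False
            continue
        edge = int(np.ceil(2.0 * a * np.sqrt(_CMOR_B / 2.0)))
        if edge > 0:
            valid[i, :edge] = False
            valid[i, N - edge :] = False
    return TimeFreqPhase(freqs, phases, valid, float(fs))


def _window_grid(n_samples: int, fs: float, window_s: float) -> np.ndarray:
    """Window centres (seconds): hop ``window_s / 2`` spanning the record."""
    hop = window_s / 2.0
    dur = n_samples / fs
    centers = np.arange(window_s / 2.0, dur - window_s / 2.0 + 1e-12, hop)
    if centers.size == 0:
        centers = np.array([dur / 2.0])
    return centers


def _windowed_resultant(
    prod_cumsum: np.ndarray,
    count_cumsum: np.ndarray,
    freqs: np.ndarray,
    fs: float,
    centers: np.ndarray,
    window_s: float,
) -> np.ndarray:
    """|mean phasor| per (frequency, window) from prefix sums; NaN when empty.

    Window length per frequency is ``max(window_s, 4 cycles)`` so slow
    rhythms are always averaged over at least four cycles.
    """
    n = count_cumsum.shape[1] - 1
    out = np.full((freqs.size, centers.size), np.nan)
    for i, f in enumerate(freqs):
        half = max(window_s, 4.0 / f) / 2.0
        a = np.clip(np.round((centers - half) * fs).astype(int), 0, n)
        b = np.clip(np.round((centers + half) * fs).astype(int), 0, n)
        counts = count_cumsum[i, b] - count_cumsum[i, a]
        sums = prod_cumsum[i, b] - prod_cumsum[i, a]
        good = counts > 0
        out[i, good] = np.abs(sums[good]) / counts[good]
    return np.clip(out, 0.0, 1.0, out=out)


def wpc(
    p1: TimeFreqPhase, p2: TimeFreqPhase, window_s: float = 1.0
) -> np.ndarray:
    """Wavelet phase coherence matrix, ``(n_freqs, n_windows)`` in [0, 1].

    Entries are the resultant length of the phase difference over each
    sliding window (50% overlap); entries with no jointly valid samples are
    NaN.
    """
    if p1.freqs.shape != p2.freqs.shape or not np.allclose(p1.freqs, p2.freqs):
        raise ValueError("phase objects must share the frequency grid")
    if p1.n_samples != p2.n_samples or p1.fs != p2.fs:
        raise ValueError("phase objects must share sample count and rate")

    valid = p1.valid_mask & p2.valid_mask
    prod = np.exp(1j * (p1.phases - p2.phases))
    prod[~valid] = 0.0
    prod_cs = np.concatenate(
        [np.zeros((p1.freqs.size, 1), complex), np.cumsum(prod, axis=1)], axis=1
    )
    count_cs = np.concatenate(
        [np.zeros((p1.freqs.size, 1), int), np.cumsum(valid, axis=1)], axis=1
    )
    centers = _window_grid(p1.n_samples, p1.fs, window_s)
    return _windowed_resultant(prod_cs, count_cs, p1.freqs, p1.fs, centers, window_s)


@dataclass
class WPCSet:
    """Pairwise WPC matrices for a full electrode set.

    ``pair_matrices`` holds one ``(n_freqs, n_windows)`` matrix per ordered
    electrode pair; the (j, i) entry is the same array object as (i, j)
    since coherence is symmetric, and the diagonal pairs are identically 1
    at valid entries.
    """

    channels: list[str]
    freqs: np.ndarray
    window_centers: np.ndarray
    pair_matrices: dict[tuple[str, str], np.ndarray]
    fs: float
    window_s: float
    duration_s: float

    def pair(self, ch1: str, ch2: str) -> np.ndarray:
        return self.pair_matrices[(canonical_label(ch1), canonical_label(ch2))]

    @property
    def n_pairs(self) -> int:
        return len(self.pair_matrices)


def pairwise_wpc(
    phases: Mapping[str, TimeFreqPhase] | Sequence[tuple[str, TimeFreqPhase]],
    window_s: float = 1.0,
) -> WPCSet:
    """WPC matrices for every ordered channel pair (n^2 matrices for n channels).

    Only the upper triangle is computed; the mirror entries share storage.
    """
    items = list(phases.items()) if isinstance(phases, Mapping) else list(phases)
    channels = [canonical_label(c) for c, _ in items]
    if len(set(channels)) != len(channels):
        raise ValueError("duplicate channel labels")
    objs = [p for _, p in items]
    ref = objs[0]
    for p in objs[1:]:
        if p.n_samples != ref.n_samples or not np.allclose(p.freqs, ref.freqs):
            raise ValueError("all phase objects must share grid and length")

    F = ref.freqs.size
    centers = _window_grid(ref.n_samples, ref.fs, window_s)
    phasors = [np.exp(1j * p.phases) * p.valid_mask for p in objs]
    masks = [p.valid_mask for p in objs]

    matrices: dict[tuple[str, str], np.ndarray] = {}
    for i in range(len(channels)):
        for j in range(i, len(channels)):
            prod = phasors[i] * np.conj(phasors[j])
            valid = masks[i] & masks[j]
            prod_cs = np.concatenate(
                [np.zeros((F, 1), complex), np.cumsum(prod, axis=1)], axis=1
            )
            count_cs = np.concatenate(
                [np.zeros((F, 1), int), np.cumsum(valid, axis=1)], axis=1
            )
            mat = _windowed_resultant(
                prod_cs, count_cs, ref.freqs, ref.fs, centers, window_s
            )
            matrices[(channels[i], channels[j])] = mat
            if i != j:
                matrices[(channels[j], channels[i])] = mat
    return WPCSet(
        channels,
        ref.freqs.copy(),
        centers,
        matrices,
        ref.fs,
        window_s,
        ref.n_samples / ref.fs,
    )


@dataclass
class WPCSummary:
    """The averaging chain: pair band means, per-electrode means, seizure mean.

    For each band, ``band_pair`` is an ``(n, n)`` matrix of time-then-
    frequency averaged coherences; ``per_electrode`` averages each row over
    the 18 off-diagonal entries; ``per_seizure`` averages the electrodes.
    """

    channels: list[str]
    bands: tuple[tuple[float, float], ...]
    band_pair: dict[tuple[float, float], np.ndarray]
    per_electrode: dict[tuple[float, float], np.ndarray]
    per_seizure: dict[tuple[float, float], float] = field(default_factory=dict)


def summarize_wpc(
    wpcset: WPCSet,
    ictal: Epoch | tuple[float, float],
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    montage: Sequence[str] | None = TEN_TWENTY_19,
) -> WPCSummary:
    """Average pair matrices over the ictal interval, bands, and electrodes.

    ``montage`` names the electrodes that must be present (the canonical 19
    by default); a missing electrode raises an error naming it.  Windows
    whose centres fall outside the ictal interval, or inside the 1 s edge
    transient of the record, are excluded.
    """
    if isinstance(ictal, Epoch):
        t0, t1 = ictal.start_s, ictal.end_s
    else:
        t0, t1 = float(ictal[0]), float(ictal[1])
    channels = list(montage) if montage is not None else list(wpcset.channels)
    for ch in channels:
        if canonical_label(ch) not in wpcset.channels:
            raise ValueError(f"electrode {ch!r} missing from the WPC set")
    channels = [canonical_label(c) for c in channels]

    lo_edge = max(t0, EDGE_TRANSIENT_S)
    hi_edge = min(t1, wpcset.duration_s - EDGE_TRANSIENT_S)
    in_ictal = (wpcset.window_centers >= lo_edge) & (wpcset.window_centers <= hi_edge)
    if not np.any(in_ictal):
        raise ValueError(
            f"no coherence windows inside the ictal interval [{t0}, {t1}] s"
        )

    n = len(channels)
    band_pair: dict[tuple[float, float], np.ndarray] = {}
    per_electrode: dict[tuple[float, float], np.ndarray] = {}
    per_seizure: dict[tuple[float, float], float] = {}
    for band in bands:
        sel = (wpcset.freqs >= band[0]) & (wpcset.freqs <= band[1])
        if not np.any(sel):
            raise ValueError(f"band {band} contains no analysis frequencies")
        mat = np.zeros((n, n))
        for i, ci in enumerate(channels):
            for j, cj in enumerate(channels):
                if j < i:
                    mat[i, j] = mat[j, i]
                    continue
                m = wpcset.pair(ci, cj)[np.ix_(sel, in_ictal)]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    mat[i, j] = float(np.nanmean(np.nanmean(m, axis=1)))
        band_pair[band] = mat
        off = mat.copy()
        np.fill_diagonal(off, np.nan)
        per_electrode[band] = np.nanmean(off, axis=1)
        per_seizure[band] = float(np.mean(per_electrode[band]))
    return WPCSummary(channels, tuple(bands), band_pair, per_electrode, per_seizure)


# ---------------------------------------------------------------------------
# n:m phase-phase coupling


def ppc(theta1: np.ndarray, theta2: np.ndarray, n: int = 1, m: int = 1) -> float:
    """n:m phase-phase coupling: ``|1/T sum_t exp(i (n th1 - m th2))|``."""
    theta1 = np.asarray(theta1, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    if theta1.size == 0 or theta2.size == 0:
        raise ValueError("empty phase series")
    if theta1.shape != theta2.shape:
        raise ValueError("phase series must have equal length")
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive integers")
    return float(np.abs(np.mean(np.exp(1j * (n * theta1 - m * theta2)))))


@dataclass
class PPCMap:
    """Cross-frequency coupling map: slow phases (rows) vs fast phases (cols)."""

    f_slow: np.ndarray
    f_fast: np.ndarray
    values: np.ndarray  # (n_slow, n_fast) in [0, 1]
    n: np.ndarray       # integer multiplier of the slow phase
    m: np.ndarray       # integer multiplier of the fast phase

    def peak(self) -> tuple[float, float, float]:
        """(f_slow, f_fast, value) of the map maximum."""
        i, j = np.unravel_index(np.nanargmax(self.values), self.values.shape)
        return float(self.f_slow[i]), float(self.f_fast[j]), float(self.values[i, j])


def _best_ratio(ratio: float, m_max: int) -> tuple[int, int]:
    """Integer n:m with m <= m_max closest to ``ratio`` (n per unit slow phase)."""
    best = (max(1, round(ratio)), 1)
    err = abs(best[0] / best[1] - ratio)
    for m in range(2, m_max + 1):
        n = max(1, round(ratio * m))
        e = abs(n / m - ratio)
        if e < err - 1e-12:
            best, err = (n, m), e
    return best


def ppc_map(
    slow_phase: TimeFreqPhase,
    fast_phase: TimeFreqPhase,
    f_slow_range: tuple[float, float] = (1.0, 30.0),
    f_fast_range: tuple[float, float] = (30.0, 100.0),
    m_max: int = 4,
) -> PPCMap:
    """n:m PPC between low frequencies of one signal and high of another.

    For every (f_slow, f_fast) grid cell the multipliers are the integer
    ratio n:m closest to ``f_fast / f_slow`` with ``m <= m_max``; coupling is
    computed over jointly valid samples.
    """
    if slow_phase.n_samples != fast_phase.n_samples:
        raise ValueError("phase objects must cover the same interval")
    rows = np.flatnonzero(
        (slow_phase.freqs >= f_slow_range[0]) & (slow_phase.freqs <= f_slow_range[1])
    )
    cols = np.flatnonzero(
        (fast_phase.freqs >= f_fast_range[0]) & (fast_phase.freqs <= f_fast_range[1])
    )
    if rows.size == 0 or cols.size == 0:
        raise ValueError("empty frequency range for the PPC map")

    values = np.full((rows.size, cols.size), np.nan)
    n_arr = np.zeros((rows.size, cols.size), dtype=int)
    m_arr = np.zeros((rows.size, cols.size), dtype=int)
    for a, ri in enumerate(rows):
        th1 = slow_phase.phases[ri]
        v1 = slow_phase.valid_mask[ri]
        f1 = slow_phase.freqs[ri]
        for b, ci in enumerate(cols):
            f2 = fast_phase.freqs[ci]
            n, m = _best_ratio(f2 / f1, m_max)
            valid = v1 & fast_phase.valid_mask[ci]
            if not np.any(valid):
                continue
            th2 = fast_phase.phases[ci]
            values[a, b] = np.abs(
                np.mean(np.exp(1j * (n * th1[valid] - m * th2[valid])))
            )
            n_arr[a, b], m_arr[a, b] = n, m
    return PPCMap(
        slow_phase.freqs[rows], fast_phase.freqs[cols], values, n_arr, m_arr
    )
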