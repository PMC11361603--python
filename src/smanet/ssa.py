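"""Singular spectrum analysis with elementary grouping.

A single-channel series ``x`` of length ``N`` is embedded into an
``L x (N - L + 1)`` Hankel trajectory matrix of lagged copies, decomposed by
thin SVD, and each rank-1 term is hankelized (anti-diagonal averaging) back
into a series of length ``N``.  With elementary grouping every rank-1 term
stays its own component, so the decomposition has exactly ``L`` components
that sum to the input.

The rank-1 hankelization is computed as a convolution: the anti-diagonal
sums of ``sigma * outer(u, v)`` are ``sigma * (u * v)`` convolved, divided by
the anti-diagonal lengths.  This keeps the per-component cost at
``O(N log N)`` instead of materialising L full matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg, signal

__all__ = ["SSADecomposition", "build_trajectory", "hankelize", "ssa_decompose"]

#: Relative cutoff below which a singular value is treated as exactly zero.
_SV_TOL = 1e-12

#: Default segmenting for long inputs: non-overlapping <= 60 s blocks joined
#: with a 1 s linear cross-fade.  SSA is linear, so the cross-fade preserves
#: the reconstruction identity exactly.
SEGMENT_S = 60.0
SEGMENT_OVERLAP_S = 1.0


@dataclass
class SSADecomposition:
    """Elementary SSA components of one channel.

    ``components`` is ``(L, N)``; row ``k`` is the hankelized rank-1 term,
    ordered by non-increasing singular value.  Rows sum to the input series.
    """

    components: np.ndarray
    singular_values: np.ndarray
    window: int
    source_channel: str = ""

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.components.shape[0] != self.window:
            raise ValueError("component count must equal the SSA window length")
        if np.any(np.diff(self.singular_values) > 1e-9 * (self.singular_values[0] + 1)):
            raise ValueError("singular values must be sorted non-increasing")

    @property
    def L(self) -> int:
        return self.window

    @property
    def n_samples(self) -> int:
        return self.components.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Sum of all components; equals the decomposed series."""
        return self.components.sum(axis=0)


def build_trajectory(x: np.ndarray, L: int) -> np.ndarray:
    """Hankel trajectory matrix, shape ``(L, N - L + 1)``; ``T[i, j] = x[i + j]``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    N = x.size
    if not 2 <= L <= N // 2:
        raise ValueError(f"window L={L} must satisfy 2 <= L <= N/2 (N={N})")
    return linalg.hankel(x[:L], x[L - 1 :])


def hankelize(matrix: np.ndarray) -> np.ndarray:
    """Average the anti-diagonals of ``matrix`` into a series of length L+K-1."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    L, K = matrix.shape
    N = L + K - 1
    out = np.zeros(N)
    for i in range(L):
        out[i : i + K] += matrix[i]
    return out / _antidiagonal_counts(L, K)


def _antidiagonal_counts(L: int, K: int) -> np.ndarray:
    N = L + K - 1
    t = np.arange(N)
    return np.minimum(np.minimum(t + 1, N - t), min(L, K))


def ssa_decompose(
    x: np.ndarray,
    L: int = 30,
    source_channel: str = "",
    segment_s: float | None = None,
    fs: float | None = None,
) -> SSADecomposition:
    """Decompose ``x`` into ``L`` elementary SSA components.

    Requires ``len(x) >= 2 L``.  A constant (or zero) series yields one
    component carrying the mean trend and ``L - 1`` exact-zero components.

    When ``segment_s`` and ``fs`` are given and the series is longer than the
    segment, the series is decomposed in blocks of ``segment_s`` seconds
    joined with a 1 s linear cross-fade; per-block component ``k`` streams
    are blended, then re-ordered globally by combined singular value.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite-valued")
    if x.size < 2 * L:
        raise ValueError(f"series length {x.size} must be >= 2L = {2 * L}")

    if segment_s is not None and fs is not None:
        seg_len = int(round(segment_s * fs))
        if x.size > seg_len:
            return _ssa_segmented(x, L, seg_len, int(round(SEGMENT_OVERLAP_S * fs)), source_channel)

    return _ssa_whole(x, L, source_channel)


def _ssa_whole(x: np.ndarray, L: int, source_channel: str) -> SSADecomposition:
    N = x.size
    T = build_trajectory(x, L)
    # thin SVD of the L x K trajectory matrix (L is small, K ~ N)
    U, s, Vt = linalg.svd(T, full_matrices=False)
    s = s.copy()
    s[s < _SV_TOL * max(s[0], np.finfo(float).tiny)] = 0.0

    counts = _antidiagonal_counts(L, N - L + 1)
    components = np.zeros((L, N))
    for k in range(L):
        if s[k] == 0.0:
            continue
        # anti-diagonal sums of the rank-1 term are a full linear convolution
        components[k] = signal.fftconvolve(s[k] * U[:, k], Vt[k]) / counts
    return SSADecomposition(components, s, L, source_channel)


def _ssa_segmented(
    x: np.ndarray, L: int, seg_len: int, overlap: int, source_channel: str
) -> SSADecomposition:
    N = x.size
    starts = list(range(0, max(N - overlap, 1), seg_len - overlap))
    # fold a too-short tail segment into its predecessor
    if len(starts) > 1 and N - starts[-1] < max(2 * L, 2 * overlap):
        starts.pop()

    components = np.zeros((L, N))
    weight = np.zeros(N)
    sv_sq = np.zeros(L)
    for si, start in enumerate(starts):
        stop = min(start + seg_len, N) if si < len(starts) - 1 else N
        seg = _ssa_whole(x[start:stop], L, source_channel)
        w = np.ones(stop - start)
        if si > 0:
            w[:overlap] = np.linspace(0.0, 1.0, overlap, endpoint=False)
        if si < len(starts) - 1:
            w[-overlap:] = 1.0 - np.linspace(0.0, 1.0, overlap, endpoint=False)
        components[:, start:stop] += seg.components * w
        weight[start:stop] += w
        sv_sq += seg.singular_values**2 * (stop - start)
    if not np.allclose(weight, 1.0):
        raise AssertionError("cross-fade weights must tile the series")

    sv = np.sqrt(sv_sq / N)
    order = np.argsort(-sv, kind="stable")
    return SSADecomposition(components[order], sv[order], L, source_channel)
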