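"""Singular spectrum analysis (SSA) denoising with bit-plane noise suppression.

A PPG is decomposed into 32 additive SSA components (SVD of the Hankel
trajectory matrix followed by anti-diagonal averaging).  Each component is
quantised to a 13-bit fixed-point word, the number of least-significant
"noise bits" is estimated from the component's own noise level, those bits
are zeroed, and the components are summed back.  A second SSA pass is then
applied and only the leading component (largest singular value) is kept as
the denoised waveform.

Because the full set of elementary matrices reconstructs the trajectory
matrix exactly, summing all 32 components returns the input signal to
floating-point precision; this property is exploited by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SSADecomposition",
    "BitPlaneConfig",
    "ssa_decompose",
    "estimate_noise_bits",
    "bitplane_zero",
    "denoise_ppg",
]

DEFAULT_WINDOW = 32


@dataclass
class SSADecomposition:
    """Result of a full-grouping SSA of a 1-D series.

    Attributes
    ----------
    components : ndarray, shape (window, n)
        Elementary reconstructed series ordered by decreasing singular
        value.  Their element-wise sum equals the input signal.
    window : int
        Embedding length L; equals the number of components.
    singular_values : ndarray, shape (window,)
        Non-negative singular values of the trajectory matrix, sorted
        non-increasing.
    """

    components: np.ndarray
    window: int
    singular_values: np.ndarray


@dataclass
class BitPlaneConfig:
    """Fixed-point representation used for bit-plane suppression.

    ``wordlength`` counts the sign bit, so magnitudes occupy
    ``wordlength - 1`` bits.  ``clamp`` bounds the admissible number of
    zeroed noise bits.
    """

    wordlength: int = 13
    clamp: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.wordlength < 2:
            raise ValueError(f"wordlength must be >= 2, got {self.wordlength}")
        if self.clamp is None:
            self.clamp = (0, self.wordlength - 1)


def ssa_decompose(signal, window: int = DEFAULT_WINDOW) -> SSADecomposition:
    """Decompose ``signal`` into ``window`` additive SSA components.

    The L x K trajectory matrix (K = n - L + 1) is factored through the
    eigendecomposition of its L x L Gram matrix, which is cheap even for
    long records.  Each eigenvector contributes one elementary matrix,
    anti-diagonally averaged back to a series of length n; the averaging
    reduces to a linear convolution of the left vector with its projected
    row, divided by the anti-diagonal counts.

    Raises
    ------
    ValueError
        If the signal is shorter than ``2 * window`` samples.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    n = x.size
    L = int(window)
    if n < 2 * L:
        raise ValueError(
            f"signal too short for SSA: need at least {2 * L} samples, got {n}"
        )
    K = n - L + 1
    # rows of traj are lagged copies: traj[i, j] = x[i + j]
    traj = sliding_window_view(x, K)  # L x K, traj[i] = x[i : i + K]
    gram = traj @ traj.T
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    singular_values = np.sqrt(eigval)

    counts = np.minimum.reduce(
        [
            np.arange(1, n + 1),
            np.arange(n, 0, -1),
            np.full(n, min(L, K)),
        ]
    ).astype(float)

    components = np.empty((L, n))
    for i in range(L):
        u = eigvec[:, i]
        row = traj.T @ u  # = s_i * v_i without an explicit division
        components[i] = np.convolve(u, row) / counts
    return SSADecomposition(components=components, window=L, singular_values=singular_values)


def estimate_noise_bits(component, cfg: BitPlaneConfig | None = None) -> int:
    """Number of least-significant bits attributed to noise in a component.

    The white-noise standard deviation is estimated robustly from first
    differences, sigma = median(|x[t+1] - x[t]|) / (0.6745 * sqrt(2)), and
    expressed in quantisation steps q of the component's own full-scale
    fixed-point grid; the bit count is floor(log2(sigma / q)), clamped.
    Degenerate inputs (all-zero, sub-quantum noise) map to 0.
    """
    cfg = cfg or BitPlaneConfig()
    x = np.asarray(component, dtype=float)
    if x.size == 0:
        raise ValueError("component must be non-empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("component must be finite")
    full_scale = float(np.max(np.abs(x)))
    if full_scale == 0.0:
        return 0
    if x.size < 2:
        return 0
    sigma = float(np.median(np.abs(np.diff(x)))) / (0.6745 * math.sqrt(2.0))
    q = full_scale / 2 ** (cfg.wordlength - 1)
    if sigma < q or sigma <= 0.0:
        return 0
    b = int(math.floor(math.log2(sigma / q)))
    lo, hi = cfg.clamp
    return int(min(max(b, lo), hi))


def bitplane_zero(component, b: int, cfg: BitPlaneConfig | None = None) -> np.ndarray:
    """Quantise a component and zero its ``b`` lowest magnitude bits.

    Symmetric fixed point: 1 sign bit plus ``wordlength - 1`` magnitude
    bits, full-scale FS = max|component| (FS = 1 for an all-zero input),
    round-to-nearest.  ``b = 0`` is plain quantisation; ``b = wordlength-1``
    clears every magnitude bit and returns zeros.
    """
    cfg = cfg or BitPlaneConfig()
    x = np.asarray(component, dtype=float)
    lo, hi = cfg.clamp
    if not (lo <= b <= hi):
        raise ValueError(f"noise bit count {b} outside permitted range [{lo}, {hi}]")
    full_scale = float(np.max(np.abs(x))) if x.size else 0.0
    if full_scale == 0.0:
        full_scale = 1.0
    mag_bits = cfg.wordlength - 1
    q = full_scale / 2**mag_bits
    codes = np.rint(x / q).astype(np.int64)
    max_code = 2**mag_bits - 1
    codes = np.clip(codes, -max_code, max_code)
    mags = np.abs(codes)
    mags = (mags >> b) << b
    return np.sign(codes) * mags * q


def denoise_ppg(
    signal,
    window: int = DEFAULT_WINDOW,
    cfg: BitPlaneConfig | None = None,
) -> np.ndarray:
    """Denoise a PPG via SSA bit-plane suppression.

    Procedure: SSA into ``window`` components; per component estimate the
    noise-bit count and zero those bit planes; sum the processed components
    into an intermediate waveform; run SSA again on it with the same window
    and return the component of largest singular value.  The output has the
    same length as the input.
    """
    cfg = cfg or BitPlaneConfig()
    x = np.asarray(signal, dtype=float)
    decomp = ssa_decompose(x, window=window)
    cleaned = np.zeros_like(x)
    for comp in decomp.components:
        b = estimate_noise_bits(comp, cfg)
        cleaned += bitplane_zero(comp, b, cfg)
    second = ssa_decompose(cleaned, window=window)
    return second.components[0]
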