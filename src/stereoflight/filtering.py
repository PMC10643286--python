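"""Low-level signal conditioning shared by the alignment and kinematics stages."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt


def lowpass_filter(
    x: np.ndarray, fs: float, cutoff: float = 100.0, order: int = 2, axis: int = 0
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    The bidirectional pass doubles the effective order and removes phase lag,
    so filtered events keep their timing relative to t = 0.  Ends are handled
    by anti-symmetric (odd) reflection padding of one filter length, which
    extends the local trend of a trajectory instead of folding it back.
    """
    if cutoff >= fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist rate {fs / 2} Hz")
    b, a = butter(order, cutoff, fs=fs)
    x = np.asarray(x, dtype=float)
    padlen = min(3 * (max(len(b), len(a)) - 1), x.shape[axis] - 1)
    return filtfilt(b, a, x, axis=axis, padtype="odd", padlen=padlen)


def upsample(x: np.ndarray, factor: int, axis: int = 0) -> np.ndarray:
    """Cubic-spline up-sampling on a uniform grid.

    Length n input becomes length ``factor * (n - 1) + 1``; the original
    samples are preserved exactly (the spline interpolates).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("upsampling factor must be a positive integer")
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if factor == 1:
        return x.copy()
    grid = np.arange(n)
    fine = np.arange(factor * (n - 1) + 1) / factor
    return CubicSpline(grid, x, axis=axis)(fine)
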