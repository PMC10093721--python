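"""Fractal-dimension estimators for waveform complexity.

Both estimators quantify how a curve's measured length grows as the
measurement scale shrinks. For a smooth line the dimension is 1; for white
noise the Higuchi dimension approaches 2.
"""

from __future__ import annotations

import numpy as np

__all__ = ["higuchi_fd", "katz_fd"]


def higuchi_fd(x, kmax: int = 10) -> float:
    """Higuchi fractal dimension.

    For each scale ``k`` in 1..kmax and offset ``m`` in 0..k−1, the
    normalized curve length is

        L_m(k) = [ Σ_i |x[m+ik] − x[m+(i−1)k]| · (N−1)/(⌊(N−1−m)/k⌋·k) ] / k

    and L(k) is the mean over offsets. The dimension is the slope of the
    least-squares fit of log L(k) against log(1/k).
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    if kmax < 2:
        raise ValueError(f"kmax must be >= 2, got {kmax}")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (((n - 1 - m) // k) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, kmax + 1)
    valid = lk > 0
    if valid.sum() < 2:
        return 1.0  # flat curve: zero length at every scale
    slope, _ = np.polyfit(np.log(1.0 / k_arr[valid]), np.log(lk[valid]), 1)
    return float(slope)


def katz_fd(x) -> float:
    """Katz fractal dimension,  FD = log10 n / (log10(d/L) + log10 n).

    ``L`` is the total path length Σ|x_{i+1} − x_i|, ``d`` the maximum
    amplitude distance from the first sample, and ``n = N − 1`` the number
    of steps. A constant signal has zero length; by convention it is a line
    and returns 1.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        raise ValueError(f"need at least 2 samples, got {len(x)}")
    steps = np.abs(np.diff(x))
    L = steps.sum()
    if L == 0:
        return 1.0
    d = np.abs(x - x[0]).max()
    n = len(x) - 1
    if d == 0:
        return 1.0
    return float(np.log10(n) / (np.log10(d / L) + np.log10(n)))
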