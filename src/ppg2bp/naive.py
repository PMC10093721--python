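"""Brute-force reference implementations of the chaotic features.

Plain-loop O(L²) versions of the entropy and fractal estimators, written
directly from their defining sums with no vectorization or shared helpers.
They exist as independent oracles: the optimized implementations in
:mod:`ppg2bp.entropy` and :mod:`ppg2bp.fractal` must agree with these to
1e-10 on short segments. Do not use them on long signals.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "sample_entropy_naive",
    "approximate_entropy_naive",
    "fuzzy_entropy_naive",
    "permutation_entropy_naive",
    "higuchi_fd_naive",
    "katz_fd_naive",
    "shannon_entropy_naive",
]


def _sd(x) -> float:
    mean = sum(x) / len(x)
    return math.sqrt(sum((v - mean) ** 2 for v in x) / len(x))


def _cheb(x, i, j, m) -> float:
    return max(abs(x[i + k] - x[j + k]) for k in range(m))


def sample_entropy_naive(x, m: int = 2, r_frac: float = 0.2) -> float:
    x = [float(v) for v in x]
    n = len(x)
    r = r_frac * _sd(x)
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if _cheb(x, i, j, m) <= r:
                b += 1
            if _cheb(x, i, j, m + 1) <= r:
                a += 1
    if b == 0:
        return 0.0
    if a == 0:
        return math.log(b + 1)
    return -math.log(a / b)


def approximate_entropy_naive(x, m: int = 2, r_frac: float = 0.2) -> float:
    x = [float(v) for v in x]
    n = len(x)
    r = r_frac * _sd(x)

    def phi(mm):
        nt = n - mm + 1
        logs = []
        for i in range(nt):
            c = 0
            for j in range(nt):
                if _cheb(x, i, j, mm) <= r:
                    c += 1
            logs.append(math.log(c / nt))
        return sum(logs) / nt

    return phi(m) - phi(m + 1)


def fuzzy_entropy_naive(x) -> float:
    a = [abs(float(v)) for v in x]
    lo, hi = min(a), max(a)
    if hi == lo:
        return 0.0
    total = 0.0
    for v in a:
        mu = (v - lo) / (hi - lo)
        for p in (mu, 1.0 - mu):
            if p > 0.0:
                total -= p * math.log(p)
    return total / len(a)


def shannon_entropy_naive(x, bins: int = 16) -> float:
    x = [float(v) for v in x]
    lo, hi = min(x), max(x)
    if lo == hi:
        return 0.0
    counts = [0] * bins
    for v in x:
        b = int((v - lo) / (hi - lo) * bins)
        counts[min(b, bins - 1)] += 1
    h = 0.0
    for c in counts:
        if c:
            p = c / len(x)
            h -= p * math.log(p)
    return h


def permutation_entropy_naive(x, order: int = 3, delay: int = 1) -> float:
    x = [float(v) for v in x]
    counts: dict[tuple, int] = {}
    n_windows = len(x) - (order - 1) * delay
    for i in range(n_windows):
        window = [x[i + j * delay] for j in range(order)]
        # stable ranking: ties broken by earlier index
        pattern = tuple(sorted(range(order), key=lambda j: (window[j], j)))
        counts[pattern] = counts.get(pattern, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n_windows
        h -= p * math.log(p)
    return h


def higuchi_fd_naive(x, kmax: int = 10) -> float:
    x = [float(v) for v in x]
    n = len(x)
    log_lk, log_inv_k = [], []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(k):
            num_int = (n - 1 - m) // k
            if num_int < 1:
                continue
            dist = 0.0
            for i in range(1, num_int + 1):
                dist += abs(x[m + i * k] - x[m + (i - 1) * k])
            lm.append(dist * (n - 1) / (num_int * k) / k)
        mean_l = sum(lm) / len(lm)
        if mean_l > 0:
            log_lk.append(math.log(mean_l))
            log_inv_k.append(math.log(1.0 / k))
    if len(log_lk) < 2:
        return 1.0
    slope, _ = np.polyfit(log_inv_k, log_lk, 1)
    return float(slope)


def katz_fd_naive(x) -> float:
    x = [float(v) for v in x]
    n_steps = len(x) - 1
    length = sum(abs(x[i + 1] - x[i]) for i in range(n_steps))
    if length == 0:
        return 1.0
    d = max(abs(v - x[0]) for v in x)
    if d == 0:
        return 1.0
    return math.log10(n_steps) / (math.log10(d / length) + math.log10(n_steps))
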