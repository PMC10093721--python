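"""Entropy estimators for physiological time series.

Sample entropy and approximate entropy are template-matching regularity
statistics: embed the series in ``m`` dimensions, count template pairs whose
Chebyshev distance is within a tolerance ``r`` (conventionally a fraction of
the signal SD), and compare the count at embedding ``m`` with the count at
``m + 1``. Regular signals keep their matches when the template grows, so
their entropy is low; irregular signals lose them.

The fuzzy entropy implemented here is the fuzzy-set (De Luca–Termini)
membership entropy of the min–max normalized absolute amplitudes — a
per-sample membership-uncertainty measure, not the template-matching FuzzyEn
variant. Shannon entropy is the amplitude-histogram entropy; permutation
entropy is the entropy of ordinal patterns of consecutive samples.

All entropies use the natural logarithm. The vectorized implementations are
checked against the brute-force loops in :mod:`ppg2bp.naive` to 1e-10.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sample_entropy",
    "approximate_entropy",
    "fuzzy_entropy",
    "shannon_entropy",
    "permutation_entropy",
]


def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    """Delay-embedding matrix of shape (n_templates, m)."""
    n = len(x) - (m - 1) * delay
    if n < 1:
        raise ValueError(f"series of length {len(x)} too short for m={m}, delay={delay}")
    idx = np.arange(n)[:, None] + np.arange(m)[None, :] * delay
    return x[idx]


def _tolerance(x: np.ndarray, r_frac: float) -> float:
    sd = float(np.std(x, ddof=0))
    return r_frac * sd


def sample_entropy(x, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy: −log(A/B) with self-matches excluded.

    ``A`` counts (m+1)-template pairs within tolerance, ``B`` counts
    m-template pairs; tolerance is ``r_frac`` times the signal SD, distances
    are Chebyshev, and matching is inclusive (d ≤ r). When no (m+1)-length
    pair matches, the conventional finite upper bound ``log(B + 1)`` is
    returned instead of infinity so feature tables stay finite.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {len(x)}")
    r = _tolerance(x, r_frac)
    limit = len(x) - m  # both counts run over the same N-m starting positions
    b = _pair_count(x, m, r, limit)
    a = _pair_count(x, m + 1, r, limit)
    if b == 0:
        return 0.0  # no m-matches at all: maximally irregular yet undefined; 0 templates
    if a == 0:
        return float(np.log(b + 1))
    return float(-np.log(a / b))


def _pair_count(x: np.ndarray, m: int, r: float, limit: int) -> int:
    """Number of unordered template pairs (i<j<limit) with Chebyshev
    distance ≤ r, for templates of length m."""
    emb = _embed(x, m)[:limit]
    limit = emb.shape[0]
    # chunked Chebyshev pairwise distances keep memory O(chunk * limit);
    # count ordered pairs including self, then convert to unordered
    total = 0
    chunk = max(1, int(2_000_000 / max(1, limit)))
    for s in range(0, limit, chunk):
        d = np.max(np.abs(emb[s : s + chunk, None, :] - emb[None, :, :]), axis=2)
        total += int((d <= r).sum())
    return (total - limit) // 2


def approximate_entropy(x, m: int = 2, r_frac: float = 0.2) -> float:
    """Approximate entropy by the standard Φ^m(r) − Φ^{m+1}(r) construction.

    Self-matches are included (so ApEn is biased but always defined).
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {len(x)}")
    r = _tolerance(x, r_frac)

    def phi(mm: int) -> float:
        emb = _embed(x, mm)
        nt = emb.shape[0]
        c = np.empty(nt)
        chunk = max(1, int(2_000_000 / max(1, nt)))
        for s in range(0, nt, chunk):
            d = np.max(np.abs(emb[s : s + chunk, None, :] - emb[None, :, :]), axis=2)
            c[s : s + d.shape[0]] = (d <= r).sum(axis=1) / nt
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def fuzzy_entropy(x) -> float:
    """Fuzzy-set membership entropy of the normalized absolute amplitudes.

    Memberships are μ_i = (|x_i| − min|x|) / (max|x| − min|x|); the value is
    the mean binary (De Luca–Termini) entropy (1/L) Σ −[μ log μ +
    (1−μ) log(1−μ)], with the 0·log 0 = 0 limit convention. A constant
    signal has degenerate normalization and returns 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    a = np.abs(x)
    lo, hi = a.min(), a.max()
    if hi == lo:
        return 0.0
    mu = (a - lo) / (hi - lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = -(mu * np.log(mu) + (1.0 - mu) * np.log(1.0 - mu))
    terms[~np.isfinite(terms)] = 0.0
    return float(terms.mean())


def shannon_entropy(x, bins: int = 16) -> float:
    """Histogram (amplitude-distribution) entropy, natural log.

    Equal-width bins over [min, max]; empty bins contribute nothing. A
    constant signal occupies a single bin and scores 0.
    """
    x = np.asarray(x, dtype=np.float64)
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    if x.min() == x.max():
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / len(x)
    return float(-(p * np.log(p)).sum())


def permutation_entropy(x, order: int = 3, delay: int = 1) -> float:
    """Ordinal-pattern entropy (unnormalized, natural log).

    Each window of ``order`` samples spaced ``delay`` apart is mapped to the
    permutation that sorts it; ties are broken by index order (stable sort),
    so earlier samples rank lower. A monotone series has a single pattern
    and entropy 0; i.i.d. noise approaches log(order!).
    """
    x = np.asarray(x, dtype=np.float64)
    if order < 2:
        raise ValueError(f"order must be >= 2, got {order}")
    if len(x) < (order - 1) * delay + 1:
        raise ValueError(
            f"series of length {len(x)} too short for order={order}, delay={delay}"
        )
    emb = _embed(x, order, delay)
    patterns = np.argsort(emb, axis=1, kind="stable")
    # encode each permutation as an integer key
    key = np.zeros(len(patterns), dtype=np.int64)
    for j in range(order):
        key = key * order + patterns[:, j]
    _, counts = np.unique(key, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())
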