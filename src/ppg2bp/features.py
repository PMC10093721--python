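"""The 24 PPG segment features: 17 time-domain and 7 chaotic.

The time-domain set is the established EMG amplitude/complexity family
(mean absolute value, waveform length, Willison amplitude, slope-sign
changes, ...) applied to preprocessed PPG segments; the chaotic set is the
entropy and fractal-dimension estimators of :mod:`ppg2bp.entropy` and
:mod:`ppg2bp.fractal`. Together they summarize pulse amplitude, slope
content and waveform complexity — the morphology axes that co-vary with
arterial pressure.

Conventions (all configurable through :class:`FeatureParams`):

* ``x_1 .. x_L`` are the segment samples (1-based in the formulas below).
* The "enhanced" features EMAV/EWL use a position-dependent exponent
  ``P_i`` = 0.75 in the central half of the segment (0.25L ≤ i ≤ 0.75L)
  and 0.5 elsewhere.
* MMAV1/MMAV2 weight the central half with 1 and taper the edges (0.5
  constant for MMAV1; linear ramps 4i/L and 4(L−i)/L for MMAV2).
* Zero-crossing and slope-sign-change thresholds default to 0; the Willison
  amplitude and myopulse thresholds default to 0.5·SD(x), which makes the
  counts invariant to the PPG gain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .entropy import (
    approximate_entropy,
    fuzzy_entropy,
    permutation_entropy,
    sample_entropy,
    shannon_entropy,
)
from .fractal import higuchi_fd, katz_fd

__all__ = [
    "FEATURE_NAMES",
    "TIME_FEATURE_NAMES",
    "CHAOTIC_FEATURE_NAMES",
    "FeatureParams",
    "time_features",
    "chaotic_features",
    "extract_all",
]

#: Canonical feature order: 17 time-domain rows then 7 chaotic rows.
TIME_FEATURE_NAMES = (
    "emav", "ewl", "mav", "wl", "zc", "ssc", "rms", "aac", "dasdv",
    "log_detector", "mmav1", "mmav2", "myop", "ssi", "var", "wamp", "mfl",
)
CHAOTIC_FEATURE_NAMES = (
    "sampen", "apen", "fuzzyen", "shannon", "permen", "higuchi_fd", "katz_fd",
)
FEATURE_NAMES = TIME_FEATURE_NAMES + CHAOTIC_FEATURE_NAMES


@dataclass(frozen=True)
class FeatureParams:
    """Tunable constants of the feature set (see module docstring)."""

    zc_threshold: float = 0.0          # absolute, signal units
    ssc_threshold: float = 0.0         # absolute, (signal units)^2
    wamp_threshold_sd: float = 0.5     # fraction of SD(x)
    myop_threshold_sd: float = 0.5     # fraction of SD(x)
    sampen_m: int = 2
    sampen_r: float = 0.2              # fraction of SD(x)
    apen_m: int = 2
    apen_r: float = 0.2                # fraction of SD(x)
    fuzzyen_r: float = 0.2             # retained for forward compatibility
    fuzzyen_n: int = 2                 # (the membership form does not use them)
    shannon_bins: int = 16
    permen_order: int = 3
    permen_delay: int = 1
    higuchi_kmax: int = 10

    def validate(self) -> None:
        if self.sampen_m < 1 or self.apen_m < 1:
            raise ValueError("embedding dimensions must be >= 1")
        if self.sampen_r <= 0 or self.apen_r <= 0 or self.fuzzyen_r <= 0:
            raise ValueError("entropy tolerances must be > 0")
        if self.shannon_bins < 2:
            raise ValueError("shannon_bins must be >= 2")
        if self.higuchi_kmax < 2:
            raise ValueError("higuchi_kmax must be >= 2")
        if self.permen_order < 2:
            raise ValueError("permen_order must be >= 2")

    def with_(self, **kwargs) -> "FeatureParams":
        return replace(self, **kwargs)


def _enhanced_exponent(L: int) -> np.ndarray:
    """P_i = 0.75 in the central half (0.25L ≤ i ≤ 0.75L, 1-based), else 0.5."""
    i = np.arange(1, L + 1)
    return np.where((i >= 0.25 * L) & (i <= 0.75 * L), 0.75, 0.5)


def _mmav1_weights(L: int) -> np.ndarray:
    i = np.arange(1, L + 1)
    return np.where((i >= 0.25 * L) & (i <= 0.75 * L), 1.0, 0.5)


def _mmav2_weights(L: int) -> np.ndarray:
    i = np.arange(1, L + 1)
    w = np.ones(L)
    low = i < 0.25 * L
    high = i > 0.75 * L
    w[low] = 4.0 * i[low] / L
    w[high] = 4.0 * (L - i[high]) / L
    return w


def time_features(x, params: FeatureParams | None = None) -> dict[str, float]:
    """The 17 time-domain features of one segment, in canonical order."""
    params = params or FeatureParams()
    x = np.asarray(x, dtype=np.float64)
    L = len(x)
    if L < 2:
        raise ValueError(f"segment must have at least 2 samples, got {L}")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite samples")

    absx = np.abs(x)
    dx = np.diff(x)
    sd = float(np.std(x, ddof=0))
    p_exp = _enhanced_exponent(L)

    out: dict[str, float] = {}
    out["emav"] = float(np.mean(absx**p_exp))
    out["ewl"] = float(np.sum(np.abs(dx) ** p_exp[1:]))
    out["mav"] = float(np.mean(absx))
    out["wl"] = float(np.sum(np.abs(dx)))
    out["zc"] = float(
        np.sum((x[:-1] * x[1:] < 0) & (np.abs(dx) >= params.zc_threshold))
    )
    out["ssc"] = float(
        np.sum((x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) > params.ssc_threshold)
    )
    out["rms"] = float(np.sqrt(np.mean(x**2)))
    out["aac"] = out["wl"] / L
    out["dasdv"] = float(np.sqrt(np.sum(dx**2) / (L - 1)))
    # log-detector: zeros floored at 1e-12 so the geometric mean stays finite
    out["log_detector"] = float(np.exp(np.mean(np.log(np.maximum(absx, 1e-12)))))
    out["mmav1"] = float(np.mean(_mmav1_weights(L) * absx))
    out["mmav2"] = float(np.mean(_mmav2_weights(L) * absx))
    out["myop"] = float(np.mean(absx > params.myop_threshold_sd * sd))
    out["ssi"] = float(np.sum(x**2))
    out["var"] = float(np.sum(x**2) / (L - 1))  # as defined: no mean subtraction
    out["wamp"] = float(np.sum(np.abs(dx) > params.wamp_threshold_sd * sd))
    out["mfl"] = float(np.log10(np.sqrt(np.sum(dx**2)))) if np.any(dx != 0) else float(
        "-inf"
    )
    if not np.isfinite(out["mfl"]):
        out["mfl"] = np.log10(1e-12)  # flat segment: floor instead of -inf
    return out


def chaotic_features(x, params: FeatureParams | None = None) -> dict[str, float]:
    """The 7 entropy/fractal features of one segment, in canonical order."""
    params = params or FeatureParams()
    params.validate()
    x = np.asarray(x, dtype=np.float64)
    return {
        "sampen": sample_entropy(x, params.sampen_m, params.sampen_r),
        "apen": approximate_entropy(x, params.apen_m, params.apen_r),
        "fuzzyen": fuzzy_entropy(x),
        "shannon": shannon_entropy(x, params.shannon_bins),
        "permen": permutation_entropy(x, params.permen_order, params.permen_delay),
        "higuchi_fd": higuchi_fd(x, params.higuchi_kmax),
        "katz_fd": katz_fd(x),
    }


def extract_all(segment, params: FeatureParams | None = None) -> dict[str, float]:
    """All 24 features of a segment (array or :class:`~ppg2bp.preprocess.Segment`).

    Returns a dict in canonical column order; every value is finite.
    Per-feature failures propagate with the feature name attached.
    """
    x = getattr(segment, "x", segment)
    params = params or FeatureParams()
    values: dict[str, float] = {}
    try:
        values.update(time_features(x, params))
    except ValueError as exc:
        raise ValueError(f"time-domain features: {exc}") from exc
    for name, fn in (
        ("sampen", lambda: sample_entropy(x, params.sampen_m, params.sampen_r)),
        ("apen", lambda: approximate_entropy(x, params.apen_m, params.apen_r)),
        ("fuzzyen", lambda: fuzzy_entropy(x)),
        ("shannon", lambda: shannon_entropy(x, params.shannon_bins)),
        ("permen", lambda: permutation_entropy(x, params.permen_order,
                                               params.permen_delay)),
        ("higuchi_fd", lambda: higuchi_fd(x, params.higuchi_kmax)),
        ("katz_fd", lambda: katz_fd(x)),
    ):
        try:
            values[name] = float(fn())
        except ValueError as exc:
            raise ValueError(f"feature {name!r}: {exc}") from exc
    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return {name: values[name] for name in FEATURE_NAMES}
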