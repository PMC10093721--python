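"""Synthetic PPG + ABP records with a known feature→pressure relationship.

The generator is a statistical stand-in for bedside waveform data, not a
hemodynamic simulation. Each record is built beat by beat:

* Per-beat morphology is drawn from Gaussians: heart period ``T`` (via the
  heart rate), pulse amplitude ``a`` and pulse width ``w``.
* The PPG channel is a sum of two Gaussians per beat — a systolic pulse and
  a delayed, smaller dicrotic pulse — plus a sub-0.5 Hz baseline-wander
  sinusoid and additive white noise.
* Per-beat SBP/DBP are **linear** functions of (a, w, T) plus small Gaussian
  noise, so a correct feature pipeline can recover the mapping and its
  achievable error is known in advance.
* The ABP channel is a piecewise pulse whose per-beat maximum lands exactly
  on the truth-table SBP at a sample, and whose minimum before each systolic
  upstroke is exactly the truth-table DBP — reference extraction can
  therefore be validated to machine precision on noise-free records.

The PPG systolic peak sits mid-beat while the ABP peak sits early in the
beat; this phase offset (peripheral pulse-arrival delay) makes the
waveform-level Pearson correlation between the two normalized channels
negative, the qualitative relationship reported for bedside recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .signal_io import WaveformRecord

__all__ = ["SynthConfig", "generate_record", "generate_dataset"]

TRUTH_COLUMNS = [
    "record", "beat", "onset_idx", "peak_idx", "period_s", "amp", "width_s",
    "sbp", "dbp",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults give a plausible resting adult record."""

    fs: float = 125.0                 # Hz
    duration: float = 60.0            # s
    hr_mean: float = 70.0             # beats/min
    hr_sd: float = 3.0                # beats/min
    pulse_amp_mean: float = 1.0       # PPG units
    pulse_amp_sd: float = 0.15
    pulse_width_mean: float = 0.14    # s (systolic Gaussian SD)
    pulse_width_sd: float = 0.012
    dicrotic_ratio: float = 0.35      # fraction of systolic amplitude
    ppg_peak_frac: float = 0.65       # systolic PPG peak position within beat
    dicrotic_delay_frac: float = 0.3  # dicrotic peak delay, fraction of beat
    baseline_amp: float = 0.3         # PPG units
    baseline_freq: float = 0.25       # Hz, must stay below 0.5
    noise_sd: float = 0.02            # PPG additive white noise
    abp_noise_sd: float = 0.0         # ABP additive white noise
    # SBP/DBP = c0 + c1*amp + c2*width + c3*period  (mmHg)
    sbp_coeffs: tuple[float, float, float, float] = (115.0, -25.0, 60.0, 10.0)
    dbp_coeffs: tuple[float, float, float, float] = (65.0, -10.0, 30.0, 5.0)
    bp_noise_sd: float = 1.0          # mmHg, noise on the linear map
    seed: int = 0

    def validate(self) -> None:
        if self.hr_mean <= 0:
            raise ValueError(f"hr_mean must be positive, got {self.hr_mean}")
        if self.fs < 25:
            raise ValueError(f"fs must be >= 25 Hz, got {self.fs}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.noise_sd < 0 or self.abp_noise_sd < 0 or self.bp_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.dicrotic_ratio < 1:
            raise ValueError(f"dicrotic_ratio must be in [0,1), got {self.dicrotic_ratio}")
        if not 0 < self.baseline_freq < 0.5:
            raise ValueError(
                f"baseline_freq must lie in (0, 0.5) Hz, got {self.baseline_freq}"
            )

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


def _draw_beats(cfg: SynthConfig, rng: np.random.Generator):
    """Beat onset times/periods/morphology covering the record duration."""
    onsets, periods, amps, widths = [], [], [], []
    t = 0.0
    while t < cfg.duration:
        hr = max(20.0, rng.normal(cfg.hr_mean, cfg.hr_sd))
        period = 60.0 / hr
        amp = max(0.1 * cfg.pulse_amp_mean, rng.normal(cfg.pulse_amp_mean,
                                                       cfg.pulse_amp_sd))
        width = max(0.03, rng.normal(cfg.pulse_width_mean, cfg.pulse_width_sd))
        onsets.append(t)
        periods.append(period)
        amps.append(amp)
        widths.append(width)
        t += period
    return (np.array(onsets), np.array(periods), np.array(amps), np.array(widths))


def generate_record(
    cfg: SynthConfig, record_index: int = 0, record_id: str | None = None
) -> tuple[WaveformRecord, pd.DataFrame]:
    """One synthetic record plus its per-beat truth table.

    Deterministic given ``(cfg.seed, record_index)``. The truth table has
    one row per fully rendered beat with the morphology draw and the exact
    SBP/DBP written into the ABP channel.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, record_index])
    n_samples = int(round(cfg.duration * cfg.fs))
    t = np.arange(n_samples) / cfg.fs

    onsets, periods, amps, widths = _draw_beats(cfg, rng)
    n_beats = len(onsets)

    # linear morphology -> pressure map (+ map noise), then validity check
    c = cfg.sbp_coeffs
    d = cfg.dbp_coeffs
    sbp = c[0] + c[1] * amps + c[2] * widths + c[3] * periods
    dbp = d[0] + d[1] * amps + d[2] * widths + d[3] * periods
    if cfg.bp_noise_sd > 0:
        sbp = sbp + rng.normal(0.0, cfg.bp_noise_sd, n_beats)
        dbp = dbp + rng.normal(0.0, cfg.bp_noise_sd, n_beats)
    if np.any(sbp <= dbp):
        raise ValueError(
            "configured BP coefficient maps produce SBP <= DBP for some beats; "
            "adjust sbp_coeffs/dbp_coeffs/bp_noise_sd"
        )

    # --- PPG: two Gaussians per beat + baseline wander + white noise -------
    ppg = np.zeros(n_samples)
    for i in range(n_beats):
        tp = onsets[i] + cfg.ppg_peak_frac * periods[i]
        td = tp + cfg.dicrotic_delay_frac * periods[i]
        ppg += amps[i] * np.exp(-0.5 * ((t - tp) / widths[i]) ** 2)
        if cfg.dicrotic_ratio > 0:
            ppg += (cfg.dicrotic_ratio * amps[i]
                    * np.exp(-0.5 * ((t - td) / (1.5 * widths[i])) ** 2))
    ppg += cfg.baseline_amp * np.sin(2 * np.pi * cfg.baseline_freq * t)
    if cfg.noise_sd > 0:
        ppg += rng.normal(0.0, cfg.noise_sd, n_samples)

    # --- ABP: exact-extremum piecewise pulse -------------------------------
    onset_idx = np.round(onsets * cfg.fs).astype(int)
    abp = np.empty(n_samples)
    abp.fill(dbp[-1])
    peak_idx = np.zeros(n_beats, dtype=int)
    keep = np.zeros(n_beats, dtype=bool)
    for i in range(n_beats):
        n0 = onset_idx[i]
        n1 = onset_idx[i + 1] if i + 1 < n_beats else n_samples
        if n1 > n_samples or n1 - n0 < 4 or n0 >= n_samples:
            break
        dbp_next = dbp[i + 1] if i + 1 < n_beats else dbp[i]
        n = n1 - n0
        k = max(1, int(round(0.3 * n)))  # systolic upstroke ends at k
        j = np.arange(n)
        up = j <= k
        beat = np.empty(n)
        beat[up] = dbp[i] + (sbp[i] - dbp[i]) * np.sin(
            0.5 * np.pi * j[up] / k) ** 2
        beat[~up] = dbp_next + (sbp[i] - dbp_next) * np.cos(
            0.5 * np.pi * (j[~up] - k) / (n - k)) ** 2
        abp[n0:n1] = beat
        peak_idx[i] = n0 + k
        keep[i] = True
    if cfg.abp_noise_sd > 0:
        abp = abp + rng.normal(0.0, cfg.abp_noise_sd, n_samples)

    rid = record_id or f"synth-{cfg.seed}-{record_index}"
    record = WaveformRecord(
        np.vstack([ppg, abp]), cfg.fs, ["PPG", "ABP"], record_id=rid
    )
    truth = pd.DataFrame({
        "record": rid,
        "beat": np.arange(n_beats)[keep],
        "onset_idx": onset_idx[keep],
        "peak_idx": peak_idx[keep],
        "period_s": periods[keep],
        "amp": amps[keep],
        "width_s": widths[keep],
        "sbp": sbp[keep],
        "dbp": dbp[keep],
    })[TRUTH_COLUMNS].reset_index(drop=True)
    return record, truth


def generate_dataset(
    cfg: SynthConfig, n_records: int
) -> tuple[list[WaveformRecord], pd.DataFrame]:
    """``n_records`` independent records and the pooled truth table.

    Record ``i`` uses the seed pair ``(cfg.seed, i)``, so records are
    mutually independent yet individually reproducible.
    """
    if n_records < 1:
        raise ValueError(f"n_records must be >= 1, got {n_records}")
    records, truths = [], []
    for i in range(n_records):
        rec, truth = generate_record(cfg, record_index=i)
        records.append(rec)
        truths.append(truth)
    return records, pd.concat(truths, ignore_index=True)
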