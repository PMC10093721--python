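"""Waveform record and feature-table I/O.

Two-channel physiological records (a PPG channel in arbitrary units and an
arterial blood pressure channel in mmHg) are the input to the pipeline.
Records can be read from a self-contained delimited-text format or from
WFDB-style header + signal files (format 16), so real waveform-database
records load unchanged. Feature tables are plain CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = [
    "WaveformRecord",
    "FeatureTable",
    "FormatError",
    "read_record",
    "write_record_csv",
    "write_record_wfdb",
    "read_feature_table",
    "write_feature_table",
    "CHANNEL_ALIASES",
]

#: Case-insensitive channel-name aliases applied on read, so common
#: waveform-database signal names map onto the pipeline's canonical labels.
CHANNEL_ALIASES = {"PLETH": "PPG", "ART": "ABP", "ABP": "ABP", "PPG": "PPG"}


class FormatError(ValueError):
    """A record or table file violates the expected on-disk format."""


def _canonical_name(name: str) -> str:
    return CHANNEL_ALIASES.get(name.strip().upper(), name.strip())


@dataclass
class WaveformRecord:
    """A multichannel uniformly sampled signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitude values, double precision. PPG is in arbitrary units,
        ABP in mmHg.
    fs : float
        Sampling frequency in Hz.
    channel_names : list of str
        Ordered unique labels; "PPG" is required for any processing,
        "ABP" additionally for training workflows.
    record_id : str
        Opaque identifier.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2:
            raise FormatError("samples must be a 2-D (channels x samples) array")
        if self.samples.shape[1] < 2:
            raise FormatError("each channel needs at least 2 samples")
        if not self.fs > 0:
            raise FormatError(f"sampling frequency must be positive, got {self.fs}")
        if len(self.channel_names) != self.samples.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError(f"channel names not unique: {self.channel_names}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by (canonical or raw) name."""
        target = _canonical_name(name)
        for i, ch in enumerate(self.channel_names):
            if _canonical_name(ch) == target:
                return self.samples[i]
        raise KeyError(f"record {self.record_id!r} has no channel {name!r}; "
                       f"channels are {self.channel_names}")

    def has_channel(self, name: str) -> bool:
        try:
            self.channel(name)
            return True
        except KeyError:
            return False


@dataclass
class FeatureTable:
    """Per-segment feature rows with paired SBP/DBP references.

    The underlying frame has one column per feature (fixed canonical order,
    see :data:`ppg2bp.features.FEATURE_NAMES`) followed by ``SBP`` and
    ``DBP`` in mmHg.
    """

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = tuple(FEATURE_NAMES) + ("SBP", "DBP")

    def __post_init__(self) -> None:
        if self.frame.empty and len(self.frame.columns) == 0:
            self.frame = pd.DataFrame(columns=list(self.COLUMNS))
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"feature table missing columns: {missing}")
        self.frame = self.frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        feats = self.frame[list(FEATURE_NAMES)]
        if len(self.frame) and feats.isna().any().any():
            bad = feats.columns[feats.isna().any()].tolist()
            raise FormatError(f"missing values in feature columns: {bad}")
        if len(self.frame):
            viol = self.frame["SBP"] <= self.frame["DBP"]
            if viol.any():
                raise FormatError(
                    f"SBP <= DBP in rows {list(self.frame.index[viol])}"
                )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """Feature matrix, shape (n_segments, 24)."""
        return self.frame[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)

    def y(self, target: str) -> np.ndarray:
        """Reference vector for ``target`` in {"SBP", "DBP"} (mmHg)."""
        t = target.upper()
        if t not in ("SBP", "DBP"):
            raise ValueError(f"target must be 'SBP' or 'DBP', got {target!r}")
        return self.frame[t].to_numpy(dtype=np.float64)


# ---------------------------------------------------------------------------
# delimited-text records:  "# fs=<Hz>" comment line, then a CSV header + body
# ---------------------------------------------------------------------------

def write_record_csv(record: WaveformRecord, path: str | os.PathLike) -> None:
    """Write a record as self-contained CSV (fs carried in a comment line)."""
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs!r}\n")
        fh.write(",".join(record.channel_names) + "\n")
        np.savetxt(fh, record.samples.T, delimiter=",", fmt="%.17g")


def _read_record_csv(path: str | os.PathLike) -> WaveformRecord:
    fs = None
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            header_lines += 1
            s = line.strip()
            if s.startswith("#"):
                body = s.lstrip("#").strip()
                if body.lower().startswith("fs"):
                    try:
                        fs = float(body.split("=", 1)[1])
                    except (IndexError, ValueError) as exc:
                        raise FormatError(f"{path}: malformed fs comment {s!r}") from exc
                continue
            names = [c.strip() for c in s.split(",")]
            break
        else:
            raise FormatError(f"{path}: no header row found")
        if fs is None:
            raise FormatError(f"{path}: sampling frequency comment '# fs=<Hz>' missing")
        rows = []
        for ln, line in enumerate(fh, start=header_lines + 1):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != len(names):
                raise FormatError(
                    f"{path}:{ln}: ragged row ({len(parts)} values, "
                    f"{len(names)} channels)"
                )
            rows.append([float(p) for p in parts])
    if len(rows) < 2:
        raise FormatError(f"{path}: fewer than 2 samples")
    samples = np.asarray(rows, dtype=np.float64).T
    names = [_canonical_name(n) for n in names]
    record_id = os.path.splitext(os.path.basename(path))[0]
    return WaveformRecord(samples, fs, names, record_id)


# ---------------------------------------------------------------------------
# minimal WFDB support: <name>.hea header + single format-16 .dat file
# ---------------------------------------------------------------------------

def write_record_wfdb(record: WaveformRecord, path: str | os.PathLike) -> None:
    """Write header (.hea) + signal (.dat) files, WFDB format 16.

    Samples are digitized with per-channel gain/baseline chosen to span the
    16-bit range; interoperability, not bit-exactness, is the goal of the
    binary path (the digitization error is bounded by half an ADC step).
    """
    path = os.fspath(path)
    base = os.path.splitext(path)[0]
    name = os.path.basename(base)
    nsig, nsamp = record.samples.shape
    gains, baselines, digital = [], [], []
    for ch in record.samples:
        lo, hi = float(np.min(ch)), float(np.max(ch))
        span = hi - lo if hi > lo else 1.0
        gain = 60000.0 / span
        # WFDB convention: physical = (digital - baseline) / gain
        baseline = -int(round(gain * (lo + hi) / 2.0))
        d = np.round(ch * gain + baseline).astype(np.int64)
        d = np.clip(d, -32768, 32767).astype("<i2")
        gains.append(gain)
        baselines.append(baseline)
        digital.append(d)
    with open(base + ".hea", "w") as fh:
        fh.write(f"{name} {nsig} {record.fs:g} {nsamp}\n")
        for i, ch_name in enumerate(record.channel_names):
            fh.write(
                f"{name}.dat 16 {gains[i]:.12g}({baselines[i]})/unit 16 0 "
                f"0 0 0 {ch_name}\n"
            )
    interleaved = np.empty(nsig * nsamp, dtype="<i2")
    for i in range(nsig):
        interleaved[i::nsig] = digital[i]
    with open(base + ".dat", "wb") as fh:
        fh.write(interleaved.tobytes())


def _read_record_wfdb(path: str | os.PathLike) -> WaveformRecord:
    path = os.fspath(path)
    base = os.path.splitext(path)[0]
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise FormatError(f"{hea}: header file not found")
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: malformed record line {lines[0]!r}")
    nsig, fs, nsamp = int(head[1]), float(head[2]), int(head[3])
    names, gains, baselines, dat_files = [], [], [], []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"{hea}: malformed signal line {ln!r}")
        dat_files.append(parts[0])
        fmt = parts[1]
        if fmt != "16":
            raise FormatError(f"{hea}: unsupported WFDB signal format {fmt!r} "
                              "(only format 16 is supported)")
        gain_spec = parts[2] if len(parts) > 2 else "200"
        gain_str = gain_spec.split("/")[0]
        if "(" in gain_str:
            g, b = gain_str.split("(")
            gain, baseline = float(g), int(b.rstrip(")"))
        else:
            gain, baseline = float(gain_str), 0
        if gain == 0:
            gain = 200.0
        gains.append(gain)
        baselines.append(baseline)
        names.append(parts[-1] if len(parts) >= 9 else f"sig{len(names)}")
    if len(set(dat_files)) != 1:
        raise FormatError(f"{hea}: multi-file records not supported")
    dat = os.path.join(os.path.dirname(base), dat_files[0])
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size < nsig * nsamp:
        raise FormatError(f"{dat}: expected {nsig * nsamp} samples, got {raw.size}")
    sig = raw[: nsig * nsamp].reshape(nsamp, nsig).T.astype(np.float64)
    for i in range(nsig):
        sig[i] = (sig[i] - baselines[i]) / gains[i]
    names = [_canonical_name(n) for n in names]
    return WaveformRecord(sig, fs, names, os.path.basename(base))


def read_record(path: str | os.PathLike, format: str = "csv") -> WaveformRecord:
    """Read a waveform record.

    Parameters
    ----------
    path : path
        For ``"csv"``, the CSV file; for ``"wfdb"``, the record base name or
        its ``.hea`` file.
    format : {"csv", "wfdb"}
    """
    if format == "csv":
        return _read_record_csv(path)
    if format == "wfdb":
        return _read_record_wfdb(path)
    raise ValueError(f"unknown record format {format!r}; use 'csv' or 'wfdb'")


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    """Write a feature table as full-precision CSV."""
    try:
        table.frame.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write feature table to {path}: {exc}") from exc


def read_feature_table(path: str | os.PathLike) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:
        raise OSError(f"cannot read feature table from {path}: {exc}") from exc
    return FeatureTable(frame)
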