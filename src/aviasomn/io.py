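"""Recording container and on-disk formats.

Electrophysiology travels as EDF (European Data Format); the hypnogram and
the brain-temperature series as UTF-8 CSV; protocol metadata as a YAML
sidecar.  EDF files are written by a small built-in writer (16-bit EDF,
one data record per second) and read back through :func:`mne.io.read_raw_edf`,
so write and read cross two independent code paths.

CSV dialects
------------
hypnogram:   ``epoch_index,start_time_iso,state,artifact`` — state tokens
             WAKE/NREM/REM, case-insensitive; artifact 0/1.
temperature: ``time_s,tbr_degC``.
"""

from __future__ import annotations

import datetime as _dt
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .protocol import (
    STATE_CODES,
    STATE_NAMES,
    ParameterError,
    Protocol,
)

__all__ = [
    "Recording",
    "Hypnogram",
    "epoch_slices",
    "write_recording",
    "read_recording",
    "write_hypnogram",
    "read_hypnogram",
    "write_tbr",
    "read_tbr",
]

REQUIRED_CHANNELS = ("eeg1", "eeg2", "emg", "accel_x", "accel_y", "accel_z")

#: EDF physical-dimension strings per channel (uV for electrophysiology,
#: g for the accelerometer axes).
_CHANNEL_UNITS = {
    "eeg1": "uV",
    "eeg2": "uV",
    "emg": "uV",
    "accel_x": "g",
    "accel_y": "g",
    "accel_z": "g",
}


class FormatError(ValueError):
    """Malformed or inconsistent on-disk data."""


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels plus an artifact mask.

    ``labels`` are int8 state codes (0 WAKE, 1 NREM, 2 REM) on the 4-s
    epoch grid anchored at the recording start; ``artifact_mask`` flags
    epochs excluded from spectral and temperature analyses.
    """

    labels: np.ndarray
    artifact_mask: np.ndarray | None = None
    epoch_len_s: float = 4.0
    provenance: str = "auto"  # manual | auto | ground_truth

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(len(self.labels), dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if len(self.artifact_mask) != len(self.labels):
            raise ParameterError("artifact mask and labels differ in length")

    def __len__(self) -> int:
        return len(self.labels)

    def state_names(self) -> np.ndarray:
        return np.asarray(STATE_NAMES)[self.labels]


@dataclass
class Recording:
    """Synchronized multi-channel recording of one bird.

    All electrophysiology channels share ``fs_signal``; the temperature
    series has its own (slower) rate.  The :class:`Protocol` carries day
    labels, light phase and the ambient-temperature trace.
    """

    channels: dict[str, np.ndarray]
    fs_signal: float
    tbr: np.ndarray | None
    fs_tbr: float
    bird_id: str
    protocol: Protocol
    start_time: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2022, 1, 10, 8, 0, 0)
    )

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channels]
        if missing:
            raise FormatError(f"missing required channel(s): {missing}")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise FormatError(f"channel lengths differ: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_signal

    @property
    def n_epochs(self) -> int:
        return int(self.duration_s // self.protocol.epoch_len_s)


def epoch_slices(rec: Recording, epoch_len_s: float | None = None):
    """Iterate per-epoch channel views: consecutive, non-overlapping
    windows anchored at the recording start; a trailing partial epoch is
    dropped.

    Yields ``(epoch_index, {channel: view})``.
    """
    epoch_len_s = epoch_len_s or rec.protocol.epoch_len_s
    spe = int(round(epoch_len_s * rec.fs_signal))
    n_epochs = rec.n_samples // spe
    for i in range(n_epochs):
        sl = slice(i * spe, (i + 1) * spe)
        yield i, {name: arr[sl] for name, arr in rec.channels.items()}


# ---------------------------------------------------------------------------
# EDF writer (16-bit, one data record per second)
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, channels: dict[str, np.ndarray], fs: float,
              start_time: _dt.datetime, patient_id: str = "X") -> None:
    """Write channels to a 16-bit EDF file with 1-s data records.

    Physical ranges are set per channel from the data (symmetric about
    zero), so the quantization step is ``range / 2**15``.
    """
    names = list(channels)
    spr = int(round(fs))  # samples per 1-s record
    n = len(channels[names[0]])
    n_records = int(np.ceil(n / spr))

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field(patient_id, 80)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field(start_time.strftime("%d.%m.%y"), 8)
    header += _edf_field(start_time.strftime("%H.%M.%S"), 8)
    header += _edf_field(str(256 * (1 + len(names))), 8)
    header += _edf_field("", 44)
    header += _edf_field(str(n_records), 8)
    header += _edf_field("1", 8)  # record duration, seconds
    header += _edf_field(str(len(names)), 4)

    phys_min, phys_max, scale = {}, {}, {}
    for name in names:
        x = np.asarray(channels[name], dtype=np.float64)
        amax = float(np.max(np.abs(x))) if x.size else 1.0
        amax = amax if amax > 0 else 1.0
        phys_min[name], phys_max[name] = -amax, amax
        scale[name] = 32767.0 / amax

    for fieldw, get in (
        (16, lambda c: c),
        (80, lambda c: "simulated"),
        (8, lambda c: _CHANNEL_UNITS.get(c, "au")),
        (8, lambda c: f"{phys_min[c]:.6g}"),
        (8, lambda c: f"{phys_max[c]:.6g}"),
        (8, lambda c: "-32767"),
        (8, lambda c: "32767"),
        (80, lambda c: ""),
        (8, lambda c: str(spr)),
        (32, lambda c: ""),
    ):
        for name in names:
            header += _edf_field(get(name), fieldw)

    digital = {}
    for name in names:
        x = np.asarray(channels[name], dtype=np.float64)
        if n_records * spr > n:
            x = np.concatenate([x, np.zeros(n_records * spr - n)])
        digital[name] = np.round(x * scale[name]).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            for name in names:
                f.write(digital[name][r * spr:(r + 1) * spr].tobytes())


def read_edf(path) -> tuple[dict[str, np.ndarray], float]:
    """Read an EDF file via :mod:`mne` and undo its unit conversion.

    Returns ``(channels, fs)`` with amplitudes in the channels' native
    physical units (uV for electrophysiology, g for the accelerometer).
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    channels = {}
    for i, name in enumerate(raw.ch_names):
        x = data[i]
        # mne rescales dimensions it recognizes to SI (uV -> V); undo
        unit = (raw._orig_units or {}).get(name, "")
        if unit in ("uV", "µV"):
            x = x * 1e6
        channels[name] = x.astype(np.float32)
    return channels, fs


# ---------------------------------------------------------------------------
# CSV + YAML sidecar
# ---------------------------------------------------------------------------

def write_hypnogram(hyp: Hypnogram, path,
                    start_time: _dt.datetime | None = None) -> None:
    start_time = start_time or _dt.datetime(2022, 1, 10, 8, 0, 0)
    times = [
        (start_time + _dt.timedelta(seconds=i * hyp.epoch_len_s)).isoformat()
        for i in range(len(hyp))
    ]
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(len(hyp)),
            "start_time_iso": times,
            "state": hyp.state_names(),
            "artifact": hyp.artifact_mask.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_hypnogram(path, epoch_len_s: float = 4.0,
                   provenance: str = "manual") -> Hypnogram:
    df = pd.read_csv(path)
    required = {"epoch_index", "state"}
    if not required.issubset(df.columns):
        raise FormatError(f"hypnogram CSV needs columns {sorted(required)}")
    idx = df["epoch_index"].to_numpy()
    if len(np.unique(idx)) != len(idx):
        raise FormatError("duplicate epoch_index in hypnogram CSV")
    expected = np.arange(len(idx))
    if not np.array_equal(np.sort(idx), expected):
        raise FormatError("hypnogram epoch_index has gaps or does not start at 0")
    df = df.sort_values("epoch_index")
    tokens = df["state"].astype(str).str.strip().str.upper()
    unknown = set(tokens.unique()) - set(STATE_NAMES)
    if unknown:
        raise FormatError(f"unknown state token(s): {sorted(unknown)}")
    labels = tokens.map(STATE_CODES).to_numpy(dtype=np.int8)
    if "artifact" in df.columns:
        mask = (
            df["artifact"].astype(str).str.strip().str.lower()
            .isin(("1", "true", "t", "yes"))
            .to_numpy()
        )
    else:
        mask = np.zeros(len(labels), dtype=bool)
    return Hypnogram(labels=labels, artifact_mask=mask,
                     epoch_len_s=epoch_len_s, provenance=provenance)


def write_tbr(tbr: np.ndarray, fs_tbr: float, path) -> None:
    t = np.arange(len(tbr)) / fs_tbr
    pd.DataFrame({"time_s": t, "tbr_degC": tbr}).to_csv(path, index=False)


def read_tbr(path) -> tuple[np.ndarray, float]:
    """Read a temperature CSV; returns ``(values, fs)`` inferred from the
    time column (must be uniform)."""
    df = pd.read_csv(path)
    if not {"time_s", "tbr_degC"}.issubset(df.columns):
        raise FormatError("temperature CSV needs columns time_s, tbr_degC")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("temperature series too short")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > 1e-6:
        raise FormatError("temperature time grid is not uniform")
    return df["tbr_degC"].to_numpy(dtype=float), 1.0 / dt[0]


# ---------------------------------------------------------------------------
# recording-level write / read
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, out_dir) -> dict[str, Path]:
    """Write signals (EDF), temperature (CSV) and metadata (YAML).

    Returns the mapping of part name to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "signals": out / f"{rec.bird_id}_signals.edf",
        "tbr": out / f"{rec.bird_id}_tbr.csv",
        "meta": out / f"{rec.bird_id}_meta.yaml",
    }
    write_edf(paths["signals"], rec.channels, rec.fs_signal, rec.start_time,
              patient_id=rec.bird_id)
    if rec.tbr is not None:
        write_tbr(rec.tbr, rec.fs_tbr, paths["tbr"])
    meta = {
        "bird_id": rec.bird_id,
        "fs_signal": rec.fs_signal,
        "fs_tbr": rec.fs_tbr,
        "n_samples": rec.n_samples,
        "start_time": rec.start_time.isoformat(),
        "protocol": rec.protocol.to_dict(),
    }
    with open(paths["meta"], "w") as f:
        yaml.safe_dump(meta, f)
    return paths


def read_recording(signal_path, tbr_path, meta_path) -> Recording:
    """Load a recording from its EDF + temperature CSV + YAML sidecar.

    A missing temperature file is allowed (temperature stages disabled);
    a missing required signal channel is an error naming the channel.
    """
    try:
        with open(meta_path) as f:
            meta = yaml.safe_load(f)
        protocol = Protocol.from_dict(meta["protocol"])
    except (OSError, KeyError, TypeError, yaml.YAMLError) as e:
        raise FormatError(f"unparsable metadata sidecar {meta_path}: {e}") from e

    channels, fs = read_edf(signal_path)
    missing = [c for c in REQUIRED_CHANNELS if c not in channels]
    if missing:
        raise FormatError(f"missing required channel(s): {missing}")
    n = int(meta["n_samples"])
    for name in channels:
        if len(channels[name]) < n:
            raise FormatError(
                f"channel {name} shorter than metadata n_samples"
            )
        channels[name] = channels[name][:n]  # drop EDF record padding

    tbr, fs_tbr = None, float(meta["fs_tbr"])
    if tbr_path is not None and Path(tbr_path).exists():
        tbr, fs_tbr = read_tbr(tbr_path)
        dur_sig = n / fs
        dur_tbr = len(tbr) / fs_tbr
        if abs(dur_sig - dur_tbr) > max(1.0 / fs, 1.0 / fs_tbr) + 1e-9:
            raise FormatError(
                f"signal ({dur_sig:.3f}s) and temperature ({dur_tbr:.3f}s) "
                "durations disagree by more than one sample"
            )

    return Recording(
        channels=channels,
        fs_signal=fs,
        tbr=tbr,
        fs_tbr=fs_tbr,
        bird_id=str(meta["bird_id"]),
        protocol=protocol,
        start_time=_dt.datetime.fromisoformat(meta["start_time"]),
    )
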