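"""Brain-temperature (Tbr) processing.

Three stages:

* per-minute averaging expressed as the deviation from the bird's own
  24 h baseline mean (corrects inter-individual offsets);
* circadian detrending: a zero-phase first-order Butterworth high-pass at
  0.000012 Hz (cutoff period 23.15 h) removes the circadian oscillation
  while leaving seconds-to-minutes state-dependent fluctuations intact
  (a literal low-pass mode is available for comparison);
* episode alignment: within each vigilance-state episode the 1-s
  temperature values are expressed relative to the value at episode
  onset, then averaged across episodes per state x night x bout-length
  stratum (<= 75 s vs > 75 s).

The filter is applied forward-backward (``sosfiltfilt``): a single causal
pass at this cutoff would lag the series by hours and corrupt episode
alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .protocol import STATE_NAMES, ParameterError, Protocol

__all__ = [
    "CircadianFilterSpec",
    "AlignedTbrCurve",
    "minute_deviation",
    "resample_to_1s",
    "circadian_filter",
    "butter_highpass_gain",
    "align_episodes",
    "bootstrap_night_difference",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CircadianFilterSpec:
    """First-order zero-phase Butterworth detrending filter.

    ``cutoff_hz`` of 0.000012 Hz corresponds to a cutoff period of
    1/0.000012 s = 23.15 h: components slower than about one day are
    removed, faster ones retained.
    """

    cutoff_hz: float = 0.000012
    order: int = 1
    mode: str = "highpass"  # "highpass" (default) or "lowpass"

    @property
    def cutoff_period_h(self) -> float:
        return 1.0 / self.cutoff_hz / 3600.0

    def validate(self) -> None:
        if self.cutoff_hz <= 0 or self.order < 1:
            raise ParameterError("cutoff must be positive, order >= 1")
        if self.mode not in ("highpass", "lowpass"):
            raise ParameterError(f"unknown filter mode {self.mode!r}")


@dataclass
class AlignedTbrCurve:
    """Mean +/- SEM relative Tbr vs time since episode onset for one
    state x night x bout-length stratum cell."""

    state: str
    night: str
    stratum: str  # "short" (<= split) or "long" (>)
    t_s: np.ndarray
    mean_degC: np.ndarray
    sem_degC: np.ndarray
    n: np.ndarray  # episodes contributing per time point


def minute_deviation(
    tbr: np.ndarray,
    fs_tbr: float,
    baseline_slice: slice,
) -> np.ndarray:
    """Non-overlapping 60-s means minus the baseline-block mean.

    ``baseline_slice`` selects the bird's baseline 24 h block in samples
    of the raw series; the returned series is in minutes.
    """
    tbr = np.asarray(tbr, dtype=float)
    spm = int(round(60.0 * fs_tbr))
    n_min = len(tbr) // spm
    minutes = tbr[: n_min * spm].reshape(n_min, spm).mean(axis=1)
    base = float(np.mean(tbr[baseline_slice]))
    return minutes - base


def resample_to_1s(tbr: np.ndarray, fs_tbr: float) -> np.ndarray:
    """Linear interpolation of the temperature series onto a 1-s grid."""
    tbr = np.asarray(tbr, dtype=float)
    if abs(fs_tbr - 1.0) < 1e-12:
        return tbr.copy()
    t_src = np.arange(len(tbr)) / fs_tbr
    t_dst = np.arange(0.0, t_src[-1] + 0.5, 1.0)
    return np.interp(t_dst, t_src, tbr)


def butter_highpass_gain(f_hz: float, spec: CircadianFilterSpec) -> float:
    """Squared magnitude response (the zero-phase two-pass gain) of the
    analytic first-order Butterworth filter at frequency ``f_hz``."""
    r = (f_hz / spec.cutoff_hz) ** (2 * spec.order)
    h2 = r / (1.0 + r) if spec.mode == "highpass" else 1.0 / (1.0 + r)
    return h2  # |H|^2: filtfilt applies the magnitude twice


def circadian_filter(
    tbr_1s: np.ndarray,
    spec: CircadianFilterSpec | None = None,
    fs: float = 1.0,
    max_gap_s: float = 300.0,
) -> np.ndarray:
    """Zero-phase circadian detrending of a 1-s temperature series.

    NaN gaps longer than ``max_gap_s`` split the series; each contiguous
    segment is filtered independently.  Segments shorter than three
    cutoff periods cannot support the filter: they are mean-subtracted
    instead and a warning is emitted.
    """
    spec = spec or CircadianFilterSpec()
    spec.validate()
    x = np.asarray(tbr_1s, dtype=float)
    out = np.full_like(x, np.nan)

    isnan = np.isnan(x)
    # segment boundaries at long NaN gaps
    segments = []
    start = None
    gap = 0
    for i, bad in enumerate(isnan):
        if bad:
            gap += 1
            if start is not None and gap * (1.0 / fs) > max_gap_s:
                segments.append((start, i - gap + 1))
                start = None
        else:
            if start is None:
                start = i
            gap = 0
    if start is not None:
        segments.append((start, len(x)))

    sos = sp_signal.butter(spec.order, spec.cutoff_hz,
                           "highpass" if spec.mode == "highpass" else "lowpass",
                           fs=fs, output="sos")
    min_len = 3.0 / spec.cutoff_hz * fs
    for s, e in segments:
        seg = x[s:e]
        nan_in = np.isnan(seg)
        if nan_in.any():  # short gaps: interpolate over them
            idx = np.arange(len(seg))
            seg = seg.copy()
            seg[nan_in] = np.interp(idx[nan_in], idx[~nan_in], seg[~nan_in])
        if len(seg) < min_len:
            warnings.warn(
                f"segment of {len(seg)} samples is shorter than three cutoff "
                "periods; falling back to mean subtraction",
                stacklevel=2,
            )
            filt = (seg - seg.mean() if spec.mode == "highpass"
                    else np.full_like(seg, seg.mean()))
        else:
            filt = sp_signal.sosfiltfilt(sos, seg)
        filt[nan_in] = np.nan
        out[s:e] = filt
    return out


def align_episodes(
    tbr_1s: np.ndarray,
    episodes: pd.DataFrame,
    artifact_mask: np.ndarray,
    protocol: Protocol,
    split_at_s: float = 75.0,
    nights: dict | None = None,
) -> list[AlignedTbrCurve]:
    """Episode-aligned relative Tbr curves.

    For every episode whose epochs are artifact-free, the 1-s values are
    expressed relative to the value at episode onset (t = 0 is exactly
    zero).  Curves are averaged across episodes per state x night x
    stratum; the short stratum is truncated at ``split_at_s``, the long
    stratum extends to the longest contributing episode.  Episodes must
    lie in a dark phase; ``nights`` maps day index -> night label
    (defaults to the protocol's day labels).
    """
    tbr_1s = np.asarray(tbr_1s, dtype=float)
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if nights is None:
        nights = dict(enumerate(protocol.day_labels))
    epoch_len = protocol.epoch_len_s

    traces: dict[tuple, list[np.ndarray]] = {}
    for _, ep in episodes.iterrows():
        s_ep = int(ep.start_epoch)
        n_ep = int(ep.n_epochs)
        if artifact_mask[s_ep:s_ep + n_ep].any():
            continue
        t0 = s_ep * epoch_len
        if not protocol.is_dark(t0):
            continue
        day = int(protocol.day_index(t0))
        dur = int(ep.duration_s)
        lo, hi = int(t0), int(t0) + dur
        if hi >= len(tbr_1s):
            hi = len(tbr_1s) - 1
            if hi <= lo:
                continue
        seg = tbr_1s[lo:hi + 1]
        if np.isnan(seg).any():
            continue
        rel = seg - seg[0]
        stratum = "short" if ep.duration_s <= split_at_s else "long"
        if stratum == "short":
            rel = rel[: int(split_at_s) + 1]
        key = (int(ep.state), nights.get(day, str(day)), stratum)
        traces.setdefault(key, []).append(rel)

    curves = []
    for (state, night, stratum), segs in sorted(
        traces.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        max_len = max(len(s) for s in segs)
        stack = np.full((len(segs), max_len), np.nan)
        for i, s in enumerate(segs):
            stack[i, : len(s)] = s
        n = np.sum(~np.isnan(stack), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stack, axis=0)
            sd = np.nanstd(stack, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        curves.append(
            AlignedTbrCurve(
                state=STATE_NAMES[state],
                night=night,
                stratum=stratum,
                t_s=np.arange(max_len, dtype=float),
                mean_degC=mean,
                sem_degC=sem,
                n=n,
            )
        )
    return curves


def bootstrap_night_difference(
    tbr_1s: np.ndarray,
    episodes: pd.DataFrame,
    artifact_mask: np.ndarray,
    protocol: Protocol,
    state: int,
    night_a: str,
    night_b: str,
    t_s: float = 20.0,
    stratum: str = "short",
    n_boot: int = 1000,
    seed: int = 0,
    split_at_s: float = 75.0,
) -> dict:
    """Bootstrap CI for the between-night difference in mean relative Tbr
    at offset ``t_s`` within episodes of one state and stratum.

    Episodes are resampled with replacement within each night
    (``n_boot`` resamples); returns the point estimate and the 2.5/97.5
    percentile interval.
    """
    rng = np.random.default_rng(seed)

    def _episode_values(night: str) -> np.ndarray:
        vals = []
        for _, ep in episodes.iterrows():
            if int(ep.state) != state:
                continue
            s_ep = int(ep.start_epoch)
            if artifact_mask[s_ep:s_ep + int(ep.n_epochs)].any():
                continue
            t0 = s_ep * protocol.epoch_len_s
            if not protocol.is_dark(t0):
                continue
            day = int(protocol.day_index(t0))
            if protocol.day_labels[day] != night:
                continue
            st = "short" if ep.duration_s <= split_at_s else "long"
            if st != stratum or ep.duration_s < t_s:
                continue
            lo = int(t0)
            if lo + int(t_s) >= len(tbr_1s):
                continue
            seg = tbr_1s[lo:lo + int(t_s) + 1]
            if np.isnan(seg).any():
                continue
            vals.append(seg[int(t_s)] - seg[0])
        return np.asarray(vals, dtype=float)

    va, vb = _episode_values(night_a), _episode_values(night_b)
    if len(va) == 0 or len(vb) == 0:
        raise ParameterError(
            f"no contributing episodes for {night_a!r} or {night_b!r}"
        )
    diff = float(va.mean() - vb.mean())
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = (
            rng.choice(va, size=len(va)).mean()
            - rng.choice(vb, size=len(vb)).mean()
        )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "difference_degC": diff,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_a": int(len(va)),
        "n_b": int(len(vb)),
        "n_boot": n_boot,
    }
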