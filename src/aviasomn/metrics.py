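"""Sleep-architecture metrics from a hypnogram.

Episode segmentation (run-length encoding of the label sequence), hourly
state percentages, per-phase sleep totals, the REM share of total sleep,
per-state episode-length statistics, and bout-length histograms with the
short (<= 75 s) / long (> 75 s) episode strata used for episode-aligned
temperature analysis.

Artifact epochs keep their scored state here: artifact exclusion applies
to spectral and temperature computations, not to time-in-state tallies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Hypnogram
from .protocol import NREM, REM, STATE_NAMES, WAKE, Protocol

__all__ = [
    "segment_episodes",
    "state_time_per_hour",
    "architecture_summary",
    "bout_length_histogram",
    "ArchitectureSummary",
]

EPISODE_COLUMNS = ("state", "start_epoch", "n_epochs", "duration_s", "block")


def segment_episodes(
    hyp: Hypnogram,
    split_at_epochs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run-length encode the label sequence into maximal same-state runs.

    ``split_at_epochs`` optionally forces episode boundaries (e.g. at
    light transitions, so episodes never span a night boundary); the
    ``block`` column then numbers the inter-boundary blocks, and episodes
    touching a forced boundary can be recognized by their block edges.

    Returns a DataFrame with columns state, start_epoch, n_epochs,
    duration_s, block.
    """
    labels = np.asarray(hyp.labels)
    n = len(labels)
    if n == 0:
        return pd.DataFrame(columns=list(EPISODE_COLUMNS))

    cuts = {0, n}
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    cuts.update(change.tolist())
    bounds = np.array([], dtype=int)
    if split_at_epochs is not None:
        bounds = np.asarray(split_at_epochs, dtype=int)
        cuts.update(b for b in bounds.tolist() if 0 < b < n)
    starts = np.array(sorted(cuts - {n}), dtype=int)
    ends = np.append(starts[1:], n)

    block = np.zeros(len(starts), dtype=int)
    if bounds.size:
        block = np.searchsorted(bounds, starts, side="right")

    return pd.DataFrame(
        {
            "state": labels[starts].astype(int),
            "start_epoch": starts,
            "n_epochs": ends - starts,
            "duration_s": (ends - starts) * hyp.epoch_len_s,
            "block": block,
        }
    )


def state_time_per_hour(hyp: Hypnogram, protocol: Protocol) -> pd.DataFrame:
    """Percentage of epochs in each state per clock hour since recording
    start.  Percentages sum to 100 over the three states."""
    eph = int(round(3600.0 / hyp.epoch_len_s))
    hour = np.arange(len(hyp)) // eph
    rows = []
    for h in np.unique(hour):
        m = hour == h
        tot = m.sum()
        pct = {
            STATE_NAMES[s]: 100.0 * np.sum(hyp.labels[m] == s) / tot
            for s in (WAKE, NREM, REM)
        }
        dark = bool(protocol.is_dark(h * 3600.0 + 1800.0))
        rows.append({"hour": int(h), "phase": "dark" if dark else "light",
                     **pct})
    return pd.DataFrame(rows)


@dataclass
class ArchitectureSummary:
    """Phase totals, REM fractions and episode-length statistics."""

    sleep_pct: dict  # {(day_label, phase): % of phase asleep}
    rem_pct_of_sleep: dict  # {(day_label, phase|"24h"): REM % of sleep}
    bout_stats: pd.DataFrame  # per night x state: mean, sem, n episodes
    hourly: pd.DataFrame


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def architecture_summary(hyp: Hypnogram, protocol: Protocol) -> ArchitectureSummary:
    """Sleep-architecture summary of one recording.

    Sleep percentages and REM fractions per protocol day and light phase;
    per-state episode-length mean +/- SEM per night (SEM across episodes
    within the night; episodes truncated by a lights transition are
    excluded from the night statistics).
    """
    labels = np.asarray(hyp.labels)
    dark = protocol.epoch_is_dark()[: len(labels)]
    day = protocol.epoch_day()[: len(labels)]

    sleep_pct: dict = {}
    rem_pct: dict = {}
    for d, lab in enumerate(protocol.day_labels):
        for phase, m_phase in (("light", ~dark), ("dark", dark)):
            m = m_phase & (day == d)
            if not m.any():
                continue
            asleep = np.isin(labels[m], (NREM, REM))
            sleep_pct[(lab, phase)] = 100.0 * asleep.mean()
            n_sleep = asleep.sum()
            if n_sleep:
                rem_pct[(lab, phase)] = (
                    100.0 * np.sum(labels[m] == REM) / n_sleep
                )
        m = day == d
        asleep = np.isin(labels[m], (NREM, REM))
        if asleep.sum():
            rem_pct[(lab, "24h")] = (
                100.0 * np.sum(labels[m] == REM) / asleep.sum()
            )

    boundaries = protocol.phase_boundaries_epochs()
    episodes = segment_episodes(hyp, split_at_epochs=boundaries)
    # restrict to whole episodes inside dark phases (night statistics)
    rows = []
    ep_dark = dark[episodes["start_epoch"].to_numpy()]
    forced = set(boundaries.tolist()) | {0, len(labels)}
    for d, lab in enumerate(protocol.day_labels):
        night = episodes[
            ep_dark & (day[episodes["start_epoch"].to_numpy()] == d)
        ]
        # drop episodes truncated by a forced boundary rather than a
        # genuine state change
        keep = []
        for _, ep in night.iterrows():
            s, e = int(ep.start_epoch), int(ep.start_epoch + ep.n_epochs)
            trunc_start = s in forced and s != 0 and s - 1 >= 0 and \
                labels[s - 1] == ep.state
            trunc_end = e in forced and e < len(labels) and \
                labels[e] == ep.state
            keep.append(not (trunc_start or trunc_end))
        night = night[np.asarray(keep, dtype=bool)] if len(night) else night
        for s in (WAKE, NREM, REM):
            dur = night.loc[night["state"] == s, "duration_s"].to_numpy()
            rows.append({
                "night": lab,
                "state": STATE_NAMES[s],
                "mean_s": float(dur.mean()) if len(dur) else float("nan"),
                "sem_s": _sem(dur),
                "n_episodes": int(len(dur)),
            })
    bout_stats = pd.DataFrame(rows)
    hourly = state_time_per_hour(hyp, protocol)
    return ArchitectureSummary(
        sleep_pct=sleep_pct,
        rem_pct_of_sleep=rem_pct,
        bout_stats=bout_stats,
        hourly=hourly,
    )


def bout_length_histogram(
    episodes: pd.DataFrame,
    bin_s: float = 4.0,
    split_at_s: float = 75.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram of episode durations on the epoch grid, per state, plus
    the sizes of the short (duration <= split_at_s) and long (>) strata.

    Returns ``(histogram, strata)`` DataFrames.
    """
    if len(episodes) == 0:
        return (
            pd.DataFrame(columns=["state", "bin_lo_s", "count"]),
            pd.DataFrame(columns=["state", "stratum", "n"]),
        )
    dur = episodes["duration_s"].to_numpy(dtype=float)
    state = episodes["state"].to_numpy()
    edges = np.arange(bin_s, dur.max() + 2 * bin_s, bin_s)
    hrows, srows = [], []
    for s in np.unique(state):
        d = dur[state == s]
        counts, _ = np.histogram(d, bins=np.r_[edges - bin_s / 2,
                                               edges[-1] + bin_s / 2])
        for lo, c in zip(edges, counts):
            if c:
                hrows.append({"state": STATE_NAMES[int(s)],
                              "bin_lo_s": float(lo), "count": int(c)})
        srows.append({"state": STATE_NAMES[int(s)], "stratum": "short",
                      "n": int(np.sum(d <= split_at_s))})
        srows.append({"state": STATE_NAMES[int(s)], "stratum": "long",
                      "n": int(np.sum(d > split_at_s))})
    return pd.DataFrame(hrows), pd.DataFrame(srows)
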