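"""Experimental protocol: day structure, light phases, ambient temperature.

The reference protocol is 72 h in a climate chamber on a 12:12 light-dark
cycle (lights on 08:00): a 24 h undisturbed baseline day at 21 degC, an
experimental day whose 12 h dark phase is a cold exposure (ambient lowered
towards ~4-5 degC), and 36 h of recovery at 21 degC.  Recordings start at
lights-on of the baseline day, so each protocol day is light phase first,
dark phase second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

# Integer vigilance-state codes used throughout the package.
WAKE: int = 0
NREM: int = 1
REM: int = 2

STATE_NAMES: tuple[str, ...] = ("WAKE", "NREM", "REM")
STATE_CODES: dict[str, int] = {name: code for code, name in enumerate(STATE_NAMES)}

LIGHT = "light"
DARK = "dark"


class ParameterError(ValueError):
    """Invalid or infeasible protocol / simulation parameters."""


@dataclass(frozen=True)
class Protocol:
    """Recording protocol: contiguous days, each split 50/50 light:dark.

    Parameters
    ----------
    day_labels : tuple of str
        One label per protocol day, in order. The label ``"cold"`` marks the
        day whose dark phase is the cold-exposure night.
    day_hours : float
        Duration of one protocol day in hours. 24 h is the study protocol;
        shorter days give scaled-down protocols for quick runs.
    epoch_len_s : float
        Scoring epoch length in seconds (4 s grid).
    fs_signal : float
        Electrophysiology sampling rate in Hz.
    fs_tbr : float
        Brain-temperature sampling rate in Hz (>= 1/60).
    lights_on_clock_h : float
        Wall-clock hour of lights-on (recording start).
    ambient_warm_degC, ambient_cold_degC : float
        Thermoneutral ambient and cold-night plateau temperatures.
    cold_ramp_fraction : float
        Fraction of the dark phase spent ramping down at the start of the
        cold night (and, mirrored, warming back up before lights-on).
        1/6 of a 12 h dark phase is a 2 h ramp.
    """

    day_labels: tuple[str, ...] = ("baseline", "cold", "recovery")
    day_hours: float = 24.0
    epoch_len_s: float = 4.0
    fs_signal: float = 100.0
    fs_tbr: float = 1.0
    lights_on_clock_h: float = 8.0
    ambient_warm_degC: float = 21.0
    ambient_cold_degC: float = 4.8
    cold_ramp_fraction: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if not self.day_labels:
            raise ParameterError("protocol needs at least one day")
        if self.day_hours <= 0:
            raise ParameterError("day_hours must be positive")
        if self.epoch_len_s <= 0 or self.fs_signal <= 0:
            raise ParameterError("epoch_len_s and fs_signal must be positive")
        if self.fs_tbr < 1.0 / 60.0:
            raise ParameterError("fs_tbr must be at least one sample per minute")
        n = self.day_hours * 3600.0 / self.epoch_len_s
        if abs(n - round(n)) > 1e-9:
            raise ParameterError("day duration must be a whole number of epochs")

    # ----- durations -------------------------------------------------
    @property
    def n_days(self) -> int:
        return len(self.day_labels)

    @property
    def day_s(self) -> float:
        return self.day_hours * 3600.0

    @property
    def total_s(self) -> float:
        return self.n_days * self.day_s

    @property
    def n_epochs(self) -> int:
        return int(round(self.total_s / self.epoch_len_s))

    @property
    def epochs_per_day(self) -> int:
        return int(round(self.day_s / self.epoch_len_s))

    @property
    def dark_s(self) -> float:
        return self.day_s / 2.0

    # ----- phase / day lookups ---------------------------------------
    def day_index(self, t_s: np.ndarray | float) -> np.ndarray:
        """Protocol day (0-based) containing time ``t_s`` since start."""
        idx = np.floor(np.asarray(t_s, dtype=float) / self.day_s).astype(int)
        return np.clip(idx, 0, self.n_days - 1)

    def is_dark(self, t_s: np.ndarray | float) -> np.ndarray:
        """True where ``t_s`` (seconds since recording start) is in darkness.

        Recordings start at lights-on, so the second half of every day is
        the dark phase.
        """
        tod = np.mod(np.asarray(t_s, dtype=float), self.day_s)
        return tod >= self.day_s / 2.0

    def light_phase(self, t_s: np.ndarray | float) -> np.ndarray:
        return np.where(self.is_dark(t_s), DARK, LIGHT)

    def epoch_times(self) -> np.ndarray:
        """Start time in seconds of every scoring epoch."""
        return np.arange(self.n_epochs) * self.epoch_len_s

    def epoch_is_dark(self) -> np.ndarray:
        return self.is_dark(self.epoch_times())

    def epoch_day(self) -> np.ndarray:
        return self.day_index(self.epoch_times())

    def phase_boundaries_epochs(self) -> np.ndarray:
        """Epoch indices at which a light<->dark transition occurs."""
        half = self.day_s / 2.0 / self.epoch_len_s
        k = np.arange(1, 2 * self.n_days)
        return np.unique(np.round(k * half).astype(int))

    # ----- ambient temperature ---------------------------------------
    def cold_day_index(self) -> int | None:
        for i, lab in enumerate(self.day_labels):
            if lab == "cold":
                return i
        return None

    def ambient(self, t_s: np.ndarray | float) -> np.ndarray:
        """Ambient temperature (degC) at time(s) ``t_s`` since start.

        Constant at the warm setpoint except during the cold night: a
        linear descent over the first ramp segment of darkness, a plateau
        at the cold setpoint, and a linear re-warming ending at lights-on.
        """
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        out = np.full(t.shape, self.ambient_warm_degC)
        ci = self.cold_day_index()
        if ci is not None:
            dark_start = ci * self.day_s + self.day_s / 2.0
            dark_len = self.day_s / 2.0
            ramp = self.cold_ramp_fraction * dark_len
            u = t - dark_start
            in_night = (u >= 0) & (u < dark_len)
            frac = np.zeros_like(t)
            frac[in_night & (u < ramp)] = u[in_night & (u < ramp)] / ramp
            plateau = in_night & (u >= ramp) & (u < dark_len - ramp)
            frac[plateau] = 1.0
            rewarm = in_night & (u >= dark_len - ramp)
            frac[rewarm] = (dark_len - u[rewarm]) / ramp
            out = out - frac * (self.ambient_warm_degC - self.ambient_cold_degC)
        if np.isscalar(t_s):
            return out[0]
        return out

    def cold_plateau_interval_s(self) -> tuple[float, float] | None:
        """(start, end) in seconds of the cold-night plateau, or None."""
        ci = self.cold_day_index()
        if ci is None:
            return None
        dark_start = ci * self.day_s + self.day_s / 2.0
        dark_len = self.day_s / 2.0
        ramp = self.cold_ramp_fraction * dark_len
        return dark_start + ramp, dark_start + dark_len - ramp

    def to_dict(self) -> dict:
        d = asdict(self)
        d["day_labels"] = list(self.day_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        d = dict(d)
        d["day_labels"] = tuple(d["day_labels"])
        return cls(**d)


#: The study protocol: baseline day, cold-night day, two recovery days.
def study_protocol(**overrides) -> Protocol:
    """Construct the default 72 h protocol (3 x 24 h; cold second night)."""
    base = dict(day_labels=("baseline", "cold", "recovery"), day_hours=24.0)
    base.update(overrides)
    return Protocol(**base)
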