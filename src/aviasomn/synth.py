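"""Synthetic 72 h polysomnography generator.

Produces ground-truth labelled recordings that mimic the statistical
structure of avian sleep under a light-dark cycle with one cold-exposure
night: strongly nocturnal sleep (~90% of the dark phase), a ~26% REM share
of total sleep, short bouts (NREM ~32 s, REM ~11 s, Wake ~50 s means at
night), state-dependent EEG amplitude and spectral shape (NREM roughly
twice the amplitude of REM/Wake, weighted towards slow frequencies),
reduced EMG tone in REM, movement on EMG + accelerometer in Wake, and a
brain-temperature series combining a circadian rhythm, mean-reverting
state-dependent drifts (REM warming, Wake cooling), a lagged cold-night
depression, and sensor noise.

Sleep architecture model
------------------------
Vigilance states follow a semi-Markov chain on {WAKE, NREM, REM} with
per-state bout lengths in whole epochs (geometric by default, so the
epoch-level process is first-order Markov).  REM is entered only from
NREM; Wake can be entered from either sleep state; Wake always returns to
NREM.  Within each light phase the transition parameters are solved so the
stationary time fractions hit the target sleep fraction exactly and the
REM share of sleep as closely as the structural constraint allows, while
keeping the configured NREM/REM bout means:

* ``a`` = P(NREM -> REM on bout end) = ``r*mN / ((1-r)*mR)`` (clamped to 1),
* the wake bout mean is kept at its configured value when the phase's wake
  budget permits, otherwise inflated (long daytime wake runs),
* ``b`` = P(REM -> NREM on bout end) absorbs the remainder.

With the default night bout means the exact REM share is marginally
infeasible under REM-only-from-NREM (each REM bout needs an NREM
predecessor); clamping yields a realized share of ~25.9% instead of 26%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .protocol import (
    WAKE,
    NREM,
    REM,
    DARK,
    ParameterError,
    Protocol,
    study_protocol,
)

__all__ = [
    "SimSleepParams",
    "SimSignalParams",
    "SimTbrParams",
    "simulate_state_sequence",
    "synthesize_signals",
    "synthesize_tbr",
    "simulate_recording",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimSleepParams:
    """Targets for the sleep-architecture simulator.

    Defaults are the baseline-night statistics of the study system:
    90.5% of the dark phase asleep, 1.6% of the light phase, REM 26% of
    total sleep, and mean bout lengths of 31.8 s (NREM), 11.1 s (REM) and
    50.3 s (Wake).
    """

    p_sleep_dark: float = 0.905
    p_sleep_light: float = 0.016
    rem_fraction: float = 0.26
    mean_bout_s: dict = field(
        default_factory=lambda: {NREM: 31.8, REM: 11.1, WAKE: 50.3}
    )
    bout_dist: str = "geometric"  # or "nbinom"
    bout_dispersion: float = 1.0  # nbinom size parameter (per-state shape)
    seed: int = 0

    def validate(self, epoch_len_s: float) -> None:
        for p, name in [
            (self.p_sleep_dark, "p_sleep_dark"),
            (self.p_sleep_light, "p_sleep_light"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.rem_fraction < 1.0:
            raise ParameterError(
                "rem_fraction must be in [0, 1); an all-REM sleep architecture "
                "is structurally impossible when REM is entered only from NREM"
            )
        for st in (WAKE, NREM, REM):
            m = self.mean_bout_s.get(st)
            if m is None or m <= epoch_len_s:
                raise ParameterError(
                    f"mean bout for state {st} must exceed the epoch length "
                    f"({epoch_len_s} s), got {m}"
                )
        if self.bout_dist not in ("geometric", "nbinom"):
            raise ParameterError(f"unknown bout distribution {self.bout_dist!r}")
        if self.bout_dispersion <= 0:
            raise ParameterError("bout_dispersion must be positive")


@dataclass(frozen=True)
class SimSignalParams:
    """Per-state signal phenomenology (amplitudes in arbitrary uV-like units)."""

    eeg_scale: dict = field(
        default_factory=lambda: {NREM: 2.0, REM: 1.0, WAKE: 1.0}
    )
    # EEG spectral shape: low-pass corner for NREM slow waves, band for the
    # activated (REM/Wake) EEG, in Hz.
    nrem_lp_hz: float = 5.0
    active_band_hz: tuple = (5.0, 30.0)
    emg_tone: dict = field(
        default_factory=lambda: {WAKE: 3.0, NREM: 1.0, REM: 0.4}
    )
    emg_burst_gain: float = 2.5  # extra EMG noise amplitude during Wake bursts
    accel_noise_sd: float = 0.005  # sensor noise (g)
    accel_move_sd: float = 0.30  # movement amplitude during Wake (g)
    artifact_rate_per_h: float = 0.0
    artifact_gain: float = 3.0

    def validate(self) -> None:
        if not (self.eeg_scale[NREM] > self.eeg_scale[REM]
                and self.eeg_scale[NREM] > self.eeg_scale[WAKE]):
            raise ParameterError("NREM EEG amplitude must exceed REM and Wake")
        if not self.emg_tone[REM] < self.emg_tone[NREM]:
            raise ParameterError("REM EMG tone must be below NREM EMG tone")
        if self.artifact_rate_per_h < 0:
            raise ParameterError("artifact_rate_per_h must be >= 0")
        if self.artifact_rate_per_h > 0 and self.artifact_gain <= 2.0:
            raise ParameterError("artifact_gain must exceed 2")


@dataclass(frozen=True)
class SimTbrParams:
    """Brain-temperature model parameters.

    ``circadian_amp_degC`` is defined as the light-phase minus dark-phase
    mean difference (2.1 degC default), not the sinusoid half-amplitude.
    Drifts are in degC/s; the OU time constant ``reversion_tau_s`` makes
    long bouts plateau (set to ``inf`` to disable mean reversion).
    ``cold_depression_degC`` is the steady-state Tbr drop once the ambient
    cold plateau and the first-order lag have settled.
    """

    base_degC: float = 41.0
    circadian_amp_degC: float = 2.1
    drift_degC_per_s: dict = field(
        default_factory=lambda: {REM: 0.004, WAKE: -0.003, NREM: -0.0005}
    )
    reversion_tau_s: float = 180.0
    cold_depression_degC: float = 1.1
    cold_lag_tau_s: float = 1800.0
    noise_sd_degC: float = 0.02

    def validate(self) -> None:
        if not (self.drift_degC_per_s[REM] > 0 > self.drift_degC_per_s[WAKE]):
            raise ParameterError("REM drift must be > 0 and Wake drift < 0")
        if self.drift_degC_per_s[NREM] > 0:
            raise ParameterError("NREM drift must be <= 0")
        if self.circadian_amp_degC < 0 or self.noise_sd_degC < 0:
            raise ParameterError("amplitude and noise SD must be >= 0")
        if self.reversion_tau_s <= 0:
            raise ParameterError("reversion_tau_s must be positive (or inf)")


# ---------------------------------------------------------------------------
# state-sequence simulation
# ---------------------------------------------------------------------------

def _phase_chain(params: SimSleepParams, epoch_len_s: float, dark: bool):
    """Solve transition parameters for one light phase.

    Returns (a, b, mean_epochs, stationary) where ``a`` = P(NREM->REM),
    ``b`` = P(REM->NREM), mean_epochs maps state -> mean bout length in
    epochs (wake possibly inflated to hit the phase's sleep fraction), and
    ``stationary`` is the time-stationary state distribution.
    """
    p = params.p_sleep_dark if dark else params.p_sleep_light
    r = params.rem_fraction
    mN = params.mean_bout_s[NREM] / epoch_len_s
    mR = params.mean_bout_s[REM] / epoch_len_s
    mW = params.mean_bout_s[WAKE] / epoch_len_s

    if p <= 0.0:
        means = {WAKE: mW, NREM: mN, REM: mR}
        return 0.0, 1.0, means, np.array([1.0, 0.0, 0.0])

    a = 0.0 if r == 0.0 else min(1.0, r * mN / ((1.0 - r) * mR))
    sleep_cycle = mN + a * mR  # expected sleep epochs per NREM-bout cycle

    if p >= 1.0:
        # no wake at all: bout ends route NREM<->REM only
        means = {WAKE: mW, NREM: mN, REM: mR}
        tN, tR = mN, a * mR
        statio = np.array([0.0, tN, tR]) / (tN + tR)
        return a, 1.0, means, statio

    wake_budget = sleep_cycle * (1.0 - p) / p  # wake epochs per cycle
    if a > 0 and wake_budget <= mW * (1.0 - a):
        # even b=1 gives too much wake at the configured bout mean:
        # shorten wake bouts (rare; not hit by defaults)
        b = 1.0
        mW_eff = wake_budget / (1.0 - a)
    elif wake_budget <= mW:
        b = (1.0 - wake_budget / mW) / a if a > 0 else 0.0
        mW_eff = mW
    else:
        # phase needs more wake than one configured bout per cycle can give
        # (light phase): inflate the wake bout mean, send every bout end to
        # wake
        b = 0.0
        mW_eff = wake_budget / 1.0 if a == 0 else wake_budget
        if a > 0:
            mW_eff = wake_budget  # with b=0: (1 - 0) * mW_eff = budget
    tW = (1.0 - a * b) * mW_eff
    tN, tR = mN, a * mR
    statio = np.array([tW, tN, tR])
    statio = statio / statio.sum()
    means = {WAKE: mW_eff, NREM: mN, REM: mR}
    return a, b, means, statio


def _draw_bout(rng: np.random.Generator, dist: str, mean_epochs: float,
               dispersion: float) -> int:
    """One bout length in whole epochs (>= 1) with the given mean."""
    if dist == "geometric":
        return int(rng.geometric(1.0 / mean_epochs))
    # negative binomial shifted to support >= 1, matched to the mean
    mu = mean_epochs - 1.0
    if mu <= 0:
        return 1
    n = dispersion
    p = n / (n + mu)
    return 1 + int(rng.negative_binomial(n, p))


def simulate_state_sequence(
    protocol: Protocol | None = None,
    params: SimSleepParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the ground-truth per-epoch vigilance-state sequence.

    Semi-Markov simulation with phase-dependent parameters; bouts are cut
    at light transitions and the state is re-drawn from the new phase's
    stationary distribution (lights-off triggers sleep onset in strongly
    nocturnal sleepers), so each phase's expected sleep fraction equals
    its target exactly.

    Returns an int8 array of state codes, one per 4-s epoch.
    """
    protocol = protocol or study_protocol()
    params = params or SimSleepParams()
    params.validate(protocol.epoch_len_s)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n_epochs = protocol.n_epochs
    labels = np.empty(n_epochs, dtype=np.int8)
    dark = protocol.epoch_is_dark()

    chains = {
        False: _phase_chain(params, protocol.epoch_len_s, dark=False),
        True: _phase_chain(params, protocol.epoch_len_s, dark=True),
    }
    p_sleep = {False: params.p_sleep_light, True: params.p_sleep_dark}

    def phase_entry_state(statio) -> int:
        # draw from the stationary time distribution; REM cannot open a
        # phase (it is entered only through NREM), so fold it into NREM
        st = int(rng.choice(3, p=statio))
        return NREM if st == REM else st

    i = 0
    cur_dark = bool(dark[0])
    a, b, means, statio = chains[cur_dark]
    state = phase_entry_state(statio)
    while i < n_epochs:
        if bool(dark[i]) != cur_dark:
            cur_dark = bool(dark[i])
            a, b, means, statio = chains[cur_dark]
            state = phase_entry_state(statio)
        n = _draw_bout(rng, params.bout_dist, means[state],
                       params.bout_dispersion)
        # truncate at phase boundary
        j = i
        end = min(i + n, n_epochs)
        while j < end and bool(dark[j]) == cur_dark:
            j += 1
        labels[i:j] = state
        i = j
        if i >= n_epochs or bool(dark[i]) != cur_dark:
            continue
        # next state from the embedded chain
        no_wake = p_sleep[cur_dark] >= 1.0
        u = rng.random()
        if state == WAKE:
            state = NREM
        elif state == NREM:
            if u < a:
                state = REM
            else:
                state = NREM if no_wake else WAKE
        else:  # REM
            state = NREM if (no_wake or u < b) else WAKE
    return labels


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _noise_gain(sos: np.ndarray, fs: float, n: int = 4096) -> float:
    """Output std of unit white noise through the filter (freq-domain)."""
    w, h = sp_signal.sosfreqz(sos, worN=n, fs=fs)
    return float(np.sqrt(np.mean(np.abs(h) ** 2)))


def _shaped_eeg(rng: np.random.Generator, n: int, fs: float,
                params: SimSignalParams) -> dict[int, np.ndarray]:
    """Unit-RMS EEG carrier per state for a series of n samples."""
    out = {}
    sos_nrem = sp_signal.butter(2, params.nrem_lp_hz, "lowpass", fs=fs,
                                output="sos")
    sos_act = sp_signal.butter(2, params.active_band_hz, "bandpass", fs=fs,
                               output="sos")
    for st, sos in ((NREM, sos_nrem), (REM, sos_act), (WAKE, sos_act)):
        white = rng.standard_normal(n)
        out[st] = sp_signal.sosfilt(sos, white) / _noise_gain(sos, fs)
    return out


def synthesize_signals(
    labels: np.ndarray,
    params: SimSignalParams | None = None,
    protocol: Protocol | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
):
    """Synthesize the six electrophysiology channels from an epoch labelling.

    Returns ``(channels, artifact_epochs)`` where ``channels`` maps
    ``eeg1, eeg2, emg, accel_x, accel_y, accel_z`` to float32 arrays at
    ``protocol.fs_signal`` and ``artifact_epochs`` is the sorted array of
    epoch indices where an artifact was injected.
    """
    protocol = protocol or study_protocol()
    params = params or SimSignalParams()
    params.validate()
    if rng is None:
        rng = np.random.default_rng(seed)

    labels = np.asarray(labels)
    if labels.ndim != 1 or len(labels) == 0:
        raise ParameterError("labels must be a non-empty 1-D array")
    bad = set(np.unique(labels)) - {WAKE, NREM, REM}
    if bad:
        raise ParameterError(f"unknown state labels: {sorted(bad)}")

    fs = protocol.fs_signal
    spe = int(round(protocol.epoch_len_s * fs))  # samples per epoch
    n_epochs = len(labels)
    n = n_epochs * spe
    state_per_sample = np.repeat(labels, spe)

    channels: dict[str, np.ndarray] = {}

    # --- EEG: state-shaped noise, amplitude-scaled per state
    amp = np.empty(n)
    for st, sc in params.eeg_scale.items():
        amp[state_per_sample == st] = sc
    for name in ("eeg1", "eeg2"):
        carriers = _shaped_eeg(rng, n, fs, params)
        eeg = np.zeros(n)
        for st in (WAKE, NREM, REM):
            m = state_per_sample == st
            eeg[m] = carriers[st][m]
        channels[name] = (eeg * amp).astype(np.float32)

    # --- EMG: tonic noise at state tone, plus movement bursts in Wake
    tone = np.empty(n)
    for st, sc in params.emg_tone.items():
        tone[state_per_sample == st] = sc
    emg = rng.standard_normal(n) * tone
    wake_epochs = np.flatnonzero(labels == WAKE)
    for e in wake_epochs:
        if rng.random() < 0.6:  # not every wake epoch has a movement burst
            dur = int(rng.uniform(0.3, 1.5) * fs)
            start = e * spe + int(rng.integers(0, max(1, spe - dur)))
            emg[start:start + dur] += (
                rng.standard_normal(min(dur, n - start))
                * params.emg_burst_gain * params.emg_tone[WAKE]
            )

    # --- accelerometer: gravity + sensor noise; movement in Wake
    gravity = {"accel_x": 0.0, "accel_y": 0.0, "accel_z": 1.0}
    move_env = np.zeros(n)
    for e in wake_epochs:
        move_env[e * spe:(e + 1) * spe] = 1.0
    sos_move = sp_signal.butter(2, 8.0, "lowpass", fs=fs, output="sos")
    for ax in ("accel_x", "accel_y", "accel_z"):
        noise = rng.standard_normal(n) * params.accel_noise_sd
        move = sp_signal.sosfilt(sos_move, rng.standard_normal(n))
        move *= params.accel_move_sd / _noise_gain(sos_move, fs)
        channels[ax] = (gravity[ax] + noise + move * move_env).astype(np.float32)

    # --- artifact injection: gross movement artifacts on all channels
    artifact_epochs = np.array([], dtype=int)
    if params.artifact_rate_per_h > 0:
        hours = n / fs / 3600.0
        n_art = rng.poisson(params.artifact_rate_per_h * hours)
        if n_art > 0:
            artifact_epochs = np.sort(
                rng.choice(n_epochs, size=min(n_art, n_epochs), replace=False)
            )
            g = params.artifact_gain
            for e in artifact_epochs:
                sl = slice(e * spe, (e + 1) * spe)
                # gross movement artifact: all channels scale together
                channels["eeg1"][sl] *= g
                channels["eeg2"][sl] *= g
                emg[sl] *= g
                burst = sp_signal.sosfilt(sos_move, rng.standard_normal(spe))
                burst *= g * params.accel_move_sd / _noise_gain(sos_move, fs)
                for ax in ("accel_x", "accel_y", "accel_z"):
                    channels[ax][sl] += burst.astype(np.float32)

    channels["emg"] = emg.astype(np.float32)
    return channels, artifact_epochs


# ---------------------------------------------------------------------------
# brain temperature
# ---------------------------------------------------------------------------

def circadian_component(t_s: np.ndarray, protocol: Protocol,
                        amp_degC: float) -> np.ndarray:
    """Circadian Tbr component: sinusoid, period one protocol day.

    Peaks mid-light, troughs mid-dark.  ``amp_degC`` is the light-minus-
    dark mean difference, so the half-amplitude is ``amp * pi / 4``
    (the mean of a cosine over the half-period centred on its peak is
    2/pi of its peak value).
    """
    half_amp = amp_degC * math.pi / 4.0
    phase = 2.0 * math.pi * (np.asarray(t_s, dtype=float)
                             - protocol.day_s / 4.0) / protocol.day_s
    return half_amp * np.cos(phase)


def synthesize_tbr(
    labels: np.ndarray,
    params: SimTbrParams | None = None,
    protocol: Protocol | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize the brain-temperature series at ``protocol.fs_tbr``.

    Tbr(t) = base + circadian sinusoid + OU-integrated state drift
    + lagged cold-night depression + white measurement noise.
    """
    protocol = protocol or study_protocol()
    params = params or SimTbrParams()
    params.validate()
    if rng is None:
        rng = np.random.default_rng(seed)

    labels = np.asarray(labels)
    dt = 1.0 / protocol.fs_tbr
    n = int(round(len(labels) * protocol.epoch_len_s * protocol.fs_tbr))
    t = np.arange(n) * dt

    tbr = params.base_degC + circadian_component(t, protocol,
                                                 params.circadian_amp_degC)

    # state-dependent drift, mean-reverting (OU) towards the circadian
    # baseline so long bouts plateau
    ep_of_sample = np.minimum(
        (t / protocol.epoch_len_s).astype(int), len(labels) - 1
    )
    drift = np.empty(n)
    for st, d in params.drift_degC_per_s.items():
        drift[labels[ep_of_sample] == st] = d
    decay = 0.0 if math.isinf(params.reversion_tau_s) else dt / params.reversion_tau_s
    # x[k] = (1 - decay) x[k-1] + dt * drift[k]  — first-order IIR
    x = sp_signal.lfilter([dt], [1.0, -(1.0 - decay)], drift)
    tbr += x

    # cold-night depression with first-order lag on the ambient deficit
    ambient = protocol.ambient(t)
    u = (protocol.ambient_warm_degC - ambient) / (
        protocol.ambient_warm_degC - protocol.ambient_cold_degC
    )
    if np.any(u > 0):
        alpha = dt / params.cold_lag_tau_s
        lag = sp_signal.lfilter([alpha], [1.0, -(1.0 - alpha)], u)
        tbr -= params.cold_depression_degC * lag

    if params.noise_sd_degC > 0:
        tbr = tbr + rng.standard_normal(n) * params.noise_sd_degC
    return tbr


# ---------------------------------------------------------------------------
# convenience: one fully-formed recording
# ---------------------------------------------------------------------------

def simulate_recording(
    protocol: Protocol | None = None,
    sleep_params: SimSleepParams | None = None,
    signal_params: SimSignalParams | None = None,
    tbr_params: SimTbrParams | None = None,
    seed: int = 0,
    bird_id: str = "sim",
):
    """Simulate labels, signals and Tbr; return ``(Recording, Hypnogram)``.

    The hypnogram carries the ground-truth labels and the injected-artifact
    mask (provenance ``ground_truth``).
    """
    from .io import Recording, Hypnogram  # local import: io depends on protocol only

    protocol = protocol or study_protocol()
    sleep_params = sleep_params or SimSleepParams(seed=seed)
    signal_params = signal_params or SimSignalParams()
    tbr_params = tbr_params or SimTbrParams()

    ss = np.random.SeedSequence([seed, sleep_params.seed])
    r_lab, r_sig, r_tbr = [np.random.default_rng(s) for s in ss.spawn(3)]

    labels = simulate_state_sequence(protocol, sleep_params, rng=r_lab)
    channels, artifact_epochs = synthesize_signals(
        labels, signal_params, protocol, rng=r_sig
    )
    tbr = synthesize_tbr(labels, tbr_params, protocol, rng=r_tbr)

    rec = Recording(
        channels=channels,
        fs_signal=protocol.fs_signal,
        tbr=tbr,
        fs_tbr=protocol.fs_tbr,
        bird_id=bird_id,
        protocol=protocol,
    )
    mask = np.zeros(len(labels), dtype=bool)
    mask[artifact_epochs] = True
    hyp = Hypnogram(labels=labels, artifact_mask=mask,
                    epoch_len_s=protocol.epoch_len_s,
                    provenance="ground_truth")
    return rec, hyp
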