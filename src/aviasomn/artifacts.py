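"""Epoch-level artifact rejection.

An epoch is flagged as artifact when its EEG amplitude exceeds twice the
undisturbed signal *in combination with* high EMG and accelerometer
activity.  "Undisturbed" is operationalized as the rolling median over
neighbouring epochs of the same vigilance state (default window 75
epochs = 5 min of same-state epochs), which keeps normal NREM slow waves
from being flagged against a Wake-dominated background.  Flagged epochs
are excluded from spectral and temperature analyses but keep their
scored state for time accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Hypnogram, Recording
from .protocol import STATE_NAMES, ParameterError
from .scoring import _robust_p2p

__all__ = ["ArtifactParams", "detect_artifacts", "epoch_envelopes"]


@dataclass(frozen=True)
class ArtifactParams:
    """Thresholds of the artifact rule.

    Factors multiply the rolling same-state median of each quantity;
    an epoch is flagged only when all three are exceeded (conjunctive
    rule; ``mode="any"`` gives the disjunctive variant).
    """

    amplitude_factor: float = 2.0
    emg_factor: float = 2.0
    accel_factor: float = 2.0
    reference_window_epochs: int = 75
    mode: str = "all"  # "all" (conjunction) or "any"

    def validate(self) -> None:
        for f, name in [
            (self.amplitude_factor, "amplitude_factor"),
            (self.emg_factor, "emg_factor"),
            (self.accel_factor, "accel_factor"),
        ]:
            if f <= 1.0:
                raise ParameterError(f"{name} must be > 1, got {f}")
        if self.reference_window_epochs < 15:
            raise ParameterError("reference window must be >= 15 epochs")
        if self.mode not in ("all", "any"):
            raise ParameterError(f"unknown mode {self.mode!r}")


def epoch_envelopes(rec: Recording, epoch_len_s: float | None = None):
    """Per-epoch EEG amplitude envelope (robust peak-to-peak, averaged
    over both EEG channels), EMG RMS and accelerometer activity."""
    epoch_len_s = epoch_len_s or rec.protocol.epoch_len_s
    fs = rec.fs_signal
    spe = int(round(epoch_len_s * fs))
    n_epochs = rec.n_samples // spe

    def epochs_of(name):
        return (rec.channels[name][: n_epochs * spe]
                .astype(np.float64).reshape(n_epochs, spe))

    env = 0.5 * (_robust_p2p(epochs_of("eeg1")) + _robust_p2p(epochs_of("eeg2")))
    emg = np.sqrt((epochs_of("emg") ** 2).mean(axis=1))
    act = np.zeros(n_epochs)
    for ax in ("accel_x", "accel_y", "accel_z"):
        act += np.abs(np.diff(epochs_of(ax), axis=1)).mean(axis=1) * fs
    act /= 3.0
    return env, emg, act


def _same_state_rolling_median(values: np.ndarray, labels: np.ndarray,
                               window: int) -> np.ndarray:
    """Centred rolling median computed within each state's subsequence."""
    out = np.empty_like(values)
    for st in np.unique(labels):
        idx = np.flatnonzero(labels == st)
        med = (
            pd.Series(values[idx])
            .rolling(window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        out[idx] = med
    return out


def detect_artifacts(
    rec: Recording,
    hyp: Hypnogram,
    params: ArtifactParams | None = None,
) -> Hypnogram:
    """Apply the artifact rule; returns a new hypnogram whose mask is the
    union of the existing mask and the newly flagged epochs."""
    params = params or ArtifactParams()
    params.validate()
    env, emg, act = epoch_envelopes(rec)
    n = len(env)
    if len(hyp) != n:
        raise ParameterError(
            f"hypnogram ({len(hyp)}) and recording ({n} epochs) misaligned"
        )
    if params.reference_window_epochs > n:
        raise ParameterError(
            f"reference window ({params.reference_window_epochs}) larger "
            f"than recording ({n} epochs)"
        )

    w = params.reference_window_epochs
    labels = hyp.labels
    ref_env = _same_state_rolling_median(env, labels, w)
    ref_emg = _same_state_rolling_median(emg, labels, w)
    ref_act = _same_state_rolling_median(act, labels, w)

    exceeds = np.column_stack([
        env > params.amplitude_factor * ref_env,
        emg > params.emg_factor * ref_emg,
        act > params.accel_factor * ref_act,
    ])
    flagged = exceeds.all(axis=1) if params.mode == "all" else exceeds.any(axis=1)

    return Hypnogram(
        labels=labels.copy(),
        artifact_mask=hyp.artifact_mask | flagged,
        epoch_len_s=hyp.epoch_len_s,
        provenance=hyp.provenance,
    )
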