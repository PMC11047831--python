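"""Trainable 3-state vigilance scoring.

Re-implements the train-then-score protocol used for avian
polysomnography: an experienced scorer labels ~100 epochs per vigilance
state of each recording, a supervised classifier is fitted on those
epochs only, and the remainder of the recording is scored automatically.
The per-state criteria map onto the feature set: NREM shows slow,
high-amplitude EEG with low EMG and no movement; REM shows fast,
low-amplitude EEG with reduced EMG; Wake shows fast EEG with high EMG and
accelerometer activity.

Features per 4-s epoch (12 dimensions):

* log EEG band power in 1.5-4, 4-8, 8-15 and 15-25 Hz, both EEG channels;
* log robust peak-to-peak EEG amplitude (2.5-97.5 percentile span), both
  channels;
* log EMG RMS;
* accelerometer activity (mean jerk magnitude over the three axes).

The default classifier is a random forest: deterministic under a fixed
seed and robust at ~100 training epochs per class; any scikit-learn
classifier can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion

from .io import Hypnogram, Recording, epoch_slices
from .protocol import STATE_NAMES, ParameterError
from .spectral import epoch_psd

__all__ = [
    "FEATURE_NAMES",
    "EpochFeatures",
    "TrainedScorer",
    "ScoringValidation",
    "extract_features",
    "select_training_epochs",
    "train_scorer",
    "score",
    "validate_scoring",
]

logger = logging.getLogger(__name__)

BANDS_HZ = ((1.5, 4.0), (4.0, 8.0), (8.0, 15.0), (15.0, 25.0))

FEATURE_NAMES = tuple(
    [f"log_p_{lo:g}_{hi:g}_eeg{ch}" for ch in (1, 2) for lo, hi in BANDS_HZ]
    + ["log_p2p_eeg1", "log_p2p_eeg2", "log_emg_rms", "accel_activity"]
)

#: Floor applied inside log() so that all-zero channels yield finite
#: features rather than -inf.
LOG_FLOOR = 1e-12


@dataclass
class EpochFeatures:
    """Fixed-dimension feature matrix, one row per epoch."""

    values: np.ndarray  # (n_epochs, len(FEATURE_NAMES))
    names: tuple = FEATURE_NAMES

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TrainedScorer:
    """A fitted epoch classifier plus its training bookkeeping."""

    model: RandomForestClassifier
    training_idx: np.ndarray
    seed: int
    class_counts: dict = field(default_factory=dict)


@dataclass
class ScoringValidation:
    """Per-state accuracy (F-measure) and the full confusion matrix.

    ``confusion[i, j]`` counts epochs whose reference state is ``i`` and
    automatic state is ``j`` (state order WAKE, NREM, REM), so row sums
    are the per-state reference epoch counts.
    """

    per_state_accuracy: dict
    confusion: np.ndarray


def _robust_p2p(x: np.ndarray, axis: int = -1) -> np.ndarray:
    hi = np.percentile(x, 97.5, axis=axis)
    lo = np.percentile(x, 2.5, axis=axis)
    return hi - lo


def extract_features(rec: Recording,
                     epoch_len_s: float | None = None) -> EpochFeatures:
    """Compute the per-epoch feature matrix for a recording."""
    epoch_len_s = epoch_len_s or rec.protocol.epoch_len_s
    fs = rec.fs_signal
    spe = int(round(epoch_len_s * fs))
    n_epochs = rec.n_samples // spe
    if n_epochs == 0:
        return EpochFeatures(values=np.empty((0, len(FEATURE_NAMES))))

    def epochs_of(name: str) -> np.ndarray:
        return (
            rec.channels[name][: n_epochs * spe]
            .astype(np.float64)
            .reshape(n_epochs, spe)
        )

    cols: list[np.ndarray] = []
    p2p: dict[int, np.ndarray] = {}
    for ch in (1, 2):
        eeg = epochs_of(f"eeg{ch}")
        if not np.any(eeg):
            logger.warning("eeg%d is all zero; features floored", ch)
        sm = epoch_psd(eeg, fs=fs)
        for lo, hi in BANDS_HZ:
            sel = (sm.freqs_hz >= lo) & (sm.freqs_hz < hi)
            cols.append(np.log(sm.power[:, sel].sum(axis=1) + LOG_FLOOR))
        p2p[ch] = np.log(_robust_p2p(eeg) + LOG_FLOOR)
    cols.append(p2p[1])
    cols.append(p2p[2])

    emg = epochs_of("emg")
    if not np.any(emg):
        logger.warning("emg is all zero; RMS floored")
    cols.append(np.log(np.sqrt((emg ** 2).mean(axis=1)) + LOG_FLOOR))

    jerk = np.zeros(n_epochs)
    for ax in ("accel_x", "accel_y", "accel_z"):
        a = epochs_of(ax)
        jerk += np.abs(np.diff(a, axis=1)).mean(axis=1) * fs
    cols.append(jerk / 3.0)

    return EpochFeatures(values=np.column_stack(cols))


def select_training_epochs(
    labels: np.ndarray,
    per_state: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Stratified random draw of training epochs: ``per_state`` per class
    (all of a class if it has fewer).  Stands in for the manual selection
    an experienced scorer would make."""
    rng = np.random.default_rng(seed)
    idx = []
    for st in range(len(STATE_NAMES)):
        pool = np.flatnonzero(np.asarray(labels) == st)
        take = min(per_state, len(pool))
        if take:
            idx.append(rng.choice(pool, size=take, replace=False))
    return np.sort(np.concatenate(idx)) if idx else np.array([], dtype=int)


def train_scorer(
    features: EpochFeatures,
    labels: np.ndarray,
    training_idx: np.ndarray,
    seed: int = 0,
    min_per_class: int = 20,
    n_estimators: int = 300,
) -> TrainedScorer:
    """Fit the epoch classifier on the labelled training subset only.

    Requires all three vigilance states in the subset and at least
    ``min_per_class`` epochs of each.
    """
    training_idx = np.asarray(training_idx, dtype=int)
    y = np.asarray(labels)[training_idx]
    found, counts = np.unique(y, return_counts=True)
    count_map = {STATE_NAMES[s]: int(c) for s, c in zip(found, counts)}
    if len(found) < len(STATE_NAMES):
        raise ParameterError(
            "training subset must contain all vigilance states; "
            f"found only {sorted(count_map)}"
        )
    short = {k: v for k, v in count_map.items() if v < min_per_class}
    if short:
        raise ParameterError(
            f"training classes below the minimum of {min_per_class}: {short}"
        )
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    model.fit(features.values[training_idx], y)
    return TrainedScorer(model=model, training_idx=training_idx, seed=seed,
                         class_counts=count_map)


def score(scorer: TrainedScorer, features: EpochFeatures,
          epoch_len_s: float = 4.0) -> Hypnogram:
    """Score every epoch; returns a hypnogram with provenance ``auto``
    and an all-false artifact mask (artifact detection is a separate
    stage)."""
    labels = scorer.model.predict(features.values).astype(np.int8)
    return Hypnogram(labels=labels, epoch_len_s=epoch_len_s,
                     provenance="auto")


def validate_scoring(auto: Hypnogram, reference: Hypnogram) -> ScoringValidation:
    """Per-state accuracy of an automatic hypnogram against a reference.

    The per-state statistic is the F-measure (harmonic mean of per-state
    precision and recall); the full confusion matrix is returned so any
    alternative agreement metric can be recomputed from it.
    """
    if len(auto) != len(reference):
        raise ParameterError(
            f"hypnogram lengths differ: {len(auto)} vs {len(reference)}"
        )
    y_ref = reference.labels
    y_auto = auto.labels
    cm = _sk_confusion(y_ref, y_auto, labels=range(len(STATE_NAMES)))
    acc = {}
    for s, name in enumerate(STATE_NAMES):
        tp = cm[s, s]
        denom = cm[s, :].sum() + cm[:, s].sum()  # 2TP + FN + FP
        acc[name] = float(2.0 * tp / denom) if denom else 0.0
    return ScoringValidation(per_state_accuracy=acc, confusion=cm)
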