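"""Feature extraction and the train-then-score protocol."""

import dataclasses

import numpy as np
import pytest

from aviasomn import NREM, REM, WAKE, simulate_recording
from aviasomn.io import Hypnogram
from aviasomn.protocol import ParameterError, Protocol
from aviasomn.scoring import (
    FEATURE_NAMES,
    EpochFeatures,
    extract_features,
    score,
    select_training_epochs,
    train_scorer,
    validate_scoring,
)
from aviasomn.synth import SimSignalParams, SimSleepParams


class TestFeatures:
    def test_sinusoid_concentrates_in_slow_band(self, short_recording):
        """A pure 2 Hz EEG epoch puts >95% of its 1.5-25 Hz power into
        the 1.5-4 Hz band feature."""
        rec, _ = short_recording
        t = np.arange(rec.n_samples) / rec.fs_signal
        sine = np.sin(2 * np.pi * 2.0 * t).astype(np.float32)
        mod = dataclasses.replace(
            rec, channels={**rec.channels, "eeg1": sine}
        )
        f = extract_features(mod)
        bands = np.exp(f.values[:, :4])  # eeg1 band powers
        assert np.all(bands[:, 0] / bands.sum(axis=1) > 0.95)

    def test_nrem_amplitude_exceeds_rem(self, short_recording):
        """NREM log-amplitude exceeds REM's in >=95% of epoch pairs."""
        rec, hyp = short_recording
        f = extract_features(rec)
        p2p1 = f.values[:, FEATURE_NAMES.index("log_p2p_eeg1")]
        a = p2p1[hyp.labels[: len(f)] == NREM]
        b = p2p1[hyp.labels[: len(f)] == REM]
        rng = np.random.default_rng(0)
        pairs = 1000
        ia = rng.integers(0, len(a), pairs)
        ib = rng.integers(0, len(b), pairs)
        assert np.mean(a[ia] > b[ib]) >= 0.95

    def test_zero_emg_floored_not_nan(self, short_recording):
        rec, _ = short_recording
        mod = dataclasses.replace(
            rec,
            channels={**rec.channels,
                      "emg": np.zeros_like(rec.channels["emg"])},
        )
        f = extract_features(mod)
        assert np.all(np.isfinite(f.values))

    def test_feature_matrix_shape(self, short_recording):
        rec, _ = short_recording
        f = extract_features(rec)
        assert f.values.shape == (rec.n_epochs, len(FEATURE_NAMES))


@pytest.fixture(scope="module")
def trained(short_recording):
    rec, hyp = short_recording
    feats = extract_features(rec)
    labels = hyp.labels[: len(feats)]
    idx = select_training_epochs(labels, per_state=100, seed=1)
    scorer = train_scorer(feats, labels, idx, seed=1)
    return feats, labels, idx, scorer


class TestTrainScore:
    def test_training_epochs_reproduced(self, trained):
        feats, labels, idx, scorer = trained
        pred = scorer.model.predict(feats.values[idx])
        assert np.mean(pred == labels[idx]) == 1.0

    def test_determinism_same_seed_same_predictions(self, trained):
        feats, labels, idx, _ = trained
        a = score(train_scorer(feats, labels, idx, seed=7), feats)
        b = score(train_scorer(feats, labels, idx, seed=7), feats)
        assert np.array_equal(a.labels, b.labels)

    def test_missing_class_rejected(self, trained):
        feats, labels, _, _ = trained
        only_two = np.flatnonzero(labels != REM)[:200]
        with pytest.raises(ParameterError, match="all vigilance states"):
            train_scorer(feats, labels, only_two, seed=0)

    def test_class_below_minimum_rejected(self, trained):
        feats, labels, _, _ = trained
        idx = np.concatenate([
            np.flatnonzero(labels == WAKE)[:100],
            np.flatnonzero(labels == NREM)[:100],
            np.flatnonzero(labels == REM)[:15],
        ])
        with pytest.raises(ParameterError, match="minimum"):
            train_scorer(feats, labels, idx, seed=0, min_per_class=20)

    def test_held_out_accuracy_high(self, trained):
        feats, labels, idx, scorer = trained
        auto = score(scorer, feats)
        val = validate_scoring(auto, Hypnogram(labels=labels))
        for state, acc in val.per_state_accuracy.items():
            assert acc >= 0.90, (state, acc)

    def test_permuted_labels_score_at_chance(self, trained):
        """Training on shuffled labels destroys the signal: held-out
        accuracy averaged over permutations falls to ~1/3."""
        feats, labels, idx, _ = trained
        held = np.setdiff1d(np.arange(len(labels)), idx)
        accs = []
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            shuffled = labels.copy()
            shuffled[idx] = rng.permutation(shuffled[idx])
            scorer = train_scorer(feats, shuffled, idx, seed=500 + rep)
            pred = scorer.model.predict(feats.values[held])
            accs.append(np.mean(pred == labels[held]))
        assert abs(np.mean(accs) - 1.0 / 3.0) < 0.10


class TestValidation:
    def test_identity_gives_unit_accuracy(self):
        h = Hypnogram(labels=np.array([0, 1, 2, 1, 0], dtype=np.int8))
        val = validate_scoring(h, h)
        assert all(v == 1.0 for v in val.per_state_accuracy.values())
        assert np.all(val.confusion == np.diag(np.diag(val.confusion)))

    def test_all_wake_against_balanced_reference(self):
        """Forced confusion matrix: WAKE F-measure 2*(1/3)/(1+1/3)=0.5,
        the other states 0."""
        ref = Hypnogram(labels=np.array([0] * 10 + [1] * 10 + [2] * 10,
                                        dtype=np.int8))
        auto = Hypnogram(labels=np.zeros(30, dtype=np.int8))
        val = validate_scoring(auto, ref)
        assert val.per_state_accuracy["WAKE"] == pytest.approx(0.5)
        assert val.per_state_accuracy["NREM"] == 0.0
        assert val.per_state_accuracy["REM"] == 0.0

    def test_single_disagreement_in_1000(self):
        ref = Hypnogram(labels=np.tile([0, 1, 2], 334)[:1000].astype(np.int8))
        auto = Hypnogram(labels=ref.labels.copy())
        auto.labels[500] = (auto.labels[500] + 1) % 3
        val = validate_scoring(auto, ref)
        assert all(v >= 0.996 for v in val.per_state_accuracy.values())

    def test_confusion_conserves_epochs(self):
        rng = np.random.default_rng(3)
        ref = Hypnogram(labels=rng.integers(0, 3, 500).astype(np.int8))
        auto = Hypnogram(labels=rng.integers(0, 3, 500).astype(np.int8))
        val = validate_scoring(auto, ref)
        assert val.confusion.sum() == 500
        counts = np.bincount(ref.labels, minlength=3)
        assert np.array_equal(val.confusion.sum(axis=1), counts)

    def test_length_mismatch_rejected(self):
        a = Hypnogram(labels=np.zeros(5, dtype=np.int8))
        b = Hypnogram(labels=np.zeros(6, dtype=np.int8))
        with pytest.raises(ParameterError):
            validate_scoring(a, b)

    def test_label_permutation_invariance(self):
        """Consistently renaming states in both hypnograms permutes the
        per-state accuracies but leaves their values unchanged."""
        rng = np.random.default_rng(9)
        ref = rng.integers(0, 3, 600).astype(np.int8)
        auto = ref.copy()
        flip = rng.random(600) < 0.1
        auto[flip] = (auto[flip] + 1) % 3
        val = validate_scoring(Hypnogram(labels=auto), Hypnogram(labels=ref))
        perm = np.array([1, 2, 0])
        val_p = validate_scoring(
            Hypnogram(labels=perm[auto].astype(np.int8)),
            Hypnogram(labels=perm[ref].astype(np.int8)),
        )
        names = ("WAKE", "NREM", "REM")
        for s in range(3):
            assert val.per_state_accuracy[names[s]] == pytest.approx(
                val_p.per_state_accuracy[names[perm[s]]]
            )


def test_accuracy_monotone_in_generator_noise():
    """Scoring accuracy does not increase as the EEG state contrast is
    drowned in noise (checked at 3 noise levels)."""
    proto = Protocol(day_labels=("baseline",), day_hours=2.0)
    overall = []
    for extra_noise in (0.0, 3.0, 12.0):
        rec, hyp = simulate_recording(proto, seed=21)
        rng = np.random.default_rng(77)
        ch = dict(rec.channels)
        for name in ("eeg1", "eeg2", "emg"):
            ch[name] = ch[name] + rng.standard_normal(
                len(ch[name])
            ).astype(np.float32) * extra_noise
        noisy = dataclasses.replace(rec, channels=ch)
        feats = extract_features(noisy)
        labels = hyp.labels[: len(feats)]
        idx = select_training_epochs(labels, per_state=60, seed=2)
        scorer = train_scorer(feats, labels, idx, seed=2)
        pred = scorer.model.predict(feats.values)
        overall.append(np.mean(pred == labels))
    assert overall[0] >= overall[1] - 0.02
    assert overall[1] >= overall[2] - 0.02
    assert overall[0] > overall[2]
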