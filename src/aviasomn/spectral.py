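"""NREM EEG spectral analysis.

Each 4-s epoch (400 samples at 100 Hz) is Hann-tapered, zero-padded to the
next power of two (512) and Fourier-transformed, giving 256 positive-
frequency bins of width fs/512 ~ 0.195 Hz (DC excluded).  Per-bin power of
clean NREM epochs is normalized to the bird's own baseline-night NREM
mean, averaged over 1.5-25 Hz, and accumulated into the cumulative NREM
sleep energy: the running sum of hourly mean power times hourly NREM
minutes.

Power scaling is mean-square per bin: with no taper and no padding the
one-sided bins (plus DC) sum to the epoch's mean-square amplitude, and the
Hann taper is compensated by its power so white-noise levels are
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import NREM, ParameterError

__all__ = [
    "SpectralMatrix",
    "EnergyCurve",
    "epoch_psd",
    "psd_frequencies",
    "normalize_to_baseline",
    "band_average",
    "hourly_power_and_energy",
]


@dataclass
class SpectralMatrix:
    """Epochs x frequency-bins power with normalization state."""

    power: np.ndarray  # (n_epochs, n_bins)
    freqs_hz: np.ndarray  # bin centre frequencies, DC excluded
    bin_width_hz: float
    normalized: bool = False
    normalization_reference: str | None = None

    @property
    def n_bins(self) -> int:
        return self.power.shape[1]


@dataclass
class EnergyCurve:
    """Hourly NREM power, NREM minutes and cumulative sleep energy."""

    table: pd.DataFrame  # columns: hour, power, nrem_min, cum_energy


def _fft_len(n_samples: int) -> int:
    return int(2 ** np.ceil(np.log2(n_samples)))


def psd_frequencies(fs: float = 100.0, n_samples: int = 400,
                    fft_len: int | None = None) -> np.ndarray:
    """Bin centre frequencies (k+1) * fs / fft_len, k = 0..fft_len/2 - 1."""
    fft_len = fft_len or _fft_len(n_samples)
    return np.arange(1, fft_len // 2 + 1) * fs / fft_len


def epoch_psd(
    epochs: np.ndarray,
    fs: float = 100.0,
    fft_len: int | None = None,
    taper: str | None = "hann",
) -> SpectralMatrix:
    """Per-epoch power spectrum: one-sided, DC excluded.

    Parameters
    ----------
    epochs : (n_epochs, n_samples) or (n_samples,) array
        4-s EEG epochs (400 samples at 100 Hz); shorter epochs are an
        error.
    fft_len : int, optional
        Defaults to the smallest power of two >= n_samples (512 for the
        standard epoch), reached by zero-padding.  ``fft_len=n_samples``
        gives the no-padding mode.
    taper : "hann" or None
        Hann taper by default; ``None`` gives the raw (Parseval-exact)
        periodogram.
    """
    x = np.atleast_2d(np.asarray(epochs, dtype=np.float64))
    n = x.shape[1]
    if n < 4 * fs - 1e-9:
        raise ParameterError(
            f"epoch shorter than 4 s: {n} samples at {fs} Hz"
        )
    fft_len = fft_len or _fft_len(n)
    if fft_len < n:
        raise ParameterError("fft_len must be >= epoch length")

    if taper == "hann":
        w = np.hanning(n)
        xw = x * w
        norm = n / np.sum(w ** 2)  # taper power compensation
    elif taper is None:
        xw = x
        norm = 1.0
    else:
        raise ParameterError(f"unknown taper {taper!r}")

    spec = np.fft.rfft(xw, n=fft_len, axis=1)
    # mean-square power per bin; one-sided doubling except DC and Nyquist
    p = (np.abs(spec) ** 2) / (fft_len * n)
    p[:, 1:-1] *= 2.0
    p = p[:, 1:] * norm  # drop DC
    freqs = psd_frequencies(fs, n, fft_len)
    return SpectralMatrix(power=p, freqs_hz=freqs,
                          bin_width_hz=fs / fft_len)


def normalize_to_baseline(
    sm: SpectralMatrix,
    reference_epochs: np.ndarray,
    reference_label: str = "baseline-night clean NREM mean",
) -> SpectralMatrix:
    """Divide each bin by the bird's baseline reference mean for that bin.

    ``reference_epochs`` is a boolean mask or index array selecting the
    reference rows of ``sm.power`` (the bird's clean NREM epochs of the
    baseline dark phase).
    """
    ref = sm.power[reference_epochs]
    if ref.size == 0:
        raise ParameterError("empty normalization reference set")
    mean = ref.mean(axis=0)
    if np.any(mean <= 0):
        raise ParameterError("non-positive reference power in some bin")
    return SpectralMatrix(
        power=sm.power / mean,
        freqs_hz=sm.freqs_hz,
        bin_width_hz=sm.bin_width_hz,
        normalized=True,
        normalization_reference=reference_label,
    )


def band_average(sm: SpectralMatrix, lo_hz: float = 1.5,
                 hi_hz: float = 25.0) -> np.ndarray:
    """Unweighted mean over bins whose centre lies in [lo_hz, hi_hz]."""
    sel = (sm.freqs_hz >= lo_hz - 1e-12) & (sm.freqs_hz <= hi_hz + 1e-12)
    if not np.any(sel):
        raise ParameterError(f"no bins in band [{lo_hz}, {hi_hz}] Hz")
    return sm.power[:, sel].mean(axis=1)


def hourly_power_and_energy(
    band_values: np.ndarray,
    labels: np.ndarray,
    artifact_mask: np.ndarray,
    epoch_len_s: float = 4.0,
    anchor_epoch: int = 0,
) -> EnergyCurve:
    """Hourly NREM power and the cumulative NREM sleep energy.

    Per clock hour (anchored at ``anchor_epoch``, e.g. lights-off for
    nighttime analyses): the mean band power over clean NREM epochs, the
    NREM time in minutes (artifact epochs keep their scored state for
    time accounting), and the running sum of power x time.  Hours with no
    clean NREM epoch have missing power and a zero energy increment.
    """
    band_values = np.asarray(band_values, dtype=float)
    labels = np.asarray(labels)
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if not (len(band_values) == len(labels) == len(artifact_mask)):
        raise ParameterError("band values, labels and mask differ in length")

    eph = int(round(3600.0 / epoch_len_s))  # epochs per hour
    idx = np.arange(len(labels)) - anchor_epoch
    hour = np.floor_divide(idx, eph)

    rows = []
    cum = 0.0
    for h in np.unique(hour):
        m = hour == h
        nrem = m & (labels == NREM)
        clean_nrem = nrem & ~artifact_mask
        nrem_min = nrem.sum() * epoch_len_s / 60.0
        if clean_nrem.any():
            p = float(band_values[clean_nrem].mean())
            cum += p * nrem_min
        else:
            p = np.nan
        rows.append((int(h), p, nrem_min, cum))
    table = pd.DataFrame(rows, columns=["hour", "power", "nrem_min",
                                        "cum_energy"])
    return EnergyCurve(table=table)
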