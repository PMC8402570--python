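"""Spectral feature extraction: mean Morlet band power per channel.

For every epoch and channel the complex Morlet wavelet transform is taken
at 1 Hz steps spanning each clinical band (delta 2-4, theta 4-7, alpha
8-12, beta 13-29, gamma 33-80 Hz by default); squared magnitude is
averaged over time and over the band's center frequencies. With 64
channels this yields 5 x 64 = 320 raw power features per epoch, which are
then log10-transformed and z-scored per feature with statistics fitted on
training epochs only.

Numerical choices
-----------------
* A complex Morlet wavelet is a Gaussian in the frequency domain, so the
  transform is computed spectrally: each epoch is reflection-padded to
  three times its length (so the slow 2 Hz wavelets keep their support
  inside the signal), FFT'd once, and multiplied by a one-sided Gaussian
  kernel per wavelet frequency. Kernels carry unit power gain at their
  center frequency (analytic-signal scaling), so a matched sinusoid's
  feature equals its variance.
* The time average of squared magnitude is evaluated by Parseval's theorem
  over the padded support, which avoids 77 inverse transforms per epoch
  and channel; it equals the epoch-window average up to seam terms of a
  few percent in the slowest band (the reflected copies carry the same
  local power as the epoch itself).
* The wavelet's spectral SD is sigma_f = max(0.6 Hz, f / 10): constant
  0.6 Hz resolution up to 6 Hz, 10 cycles above. The conventional 3-7
  cycle rules give multi-Hz widths at low frequencies, which bleeds delta
  into theta and theta into alpha; the constant low-frequency resolution
  keeps adjacent clinical bands separable.
* Adjacent clinical bands share edge frequencies (delta ends at 4 Hz,
  theta starts there), so wavelet grids are half-open, [f_lo, f_hi) --
  delta uses {2, 3} Hz, theta {4, 5, 6}, and so on -- which assigns each
  grid frequency to exactly one band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from vigil.config import DEFAULT_BANDS, BandDef
from vigil.data import EpochSet

LOG_EPS = 1e-12
_CHUNK = 128
#: spectral-resolution floor (Hz) and maximum cycle count of the wavelets
SIGMA_F_FLOOR = 0.6
MAX_CYCLES = 10.0


class SpectralError(ValueError):
    pass


def wavelet_sigma_f(freq: float) -> float:
    """Spectral SD (Hz) of the Morlet wavelet centered at ``freq``."""
    return max(SIGMA_F_FLOOR, freq / MAX_CYCLES)


def wavelet_n_cycles(freq: float) -> float:
    """Equivalent cycle count n = f / sigma_f of the wavelet at ``freq``."""
    return freq / wavelet_sigma_f(freq)


def band_frequencies(band: BandDef, freq_step: float = 1.0) -> np.ndarray:
    """Wavelet center frequencies on the half-open grid [f_lo, f_hi)."""
    f = np.arange(band.f_lo, band.f_hi - 1e-9, freq_step)
    if f.size == 0:
        raise SpectralError(f"band {band.name!r} spans no wavelet frequencies")
    return f


@dataclass
class FeatureTransform:
    """Per-feature log + z-scoring state fitted on training epochs."""

    mean: np.ndarray
    sd: np.ndarray
    log_eps: float = LOG_EPS


@dataclass
class SpectralFeatureMatrix:
    """``values[epoch, feature]`` with ``feature_index[(channel, band)]``.

    ``values`` holds raw band power until :func:`log_and_standardize` is
    applied, after which ``log_applied`` is set and ``transform`` carries
    the fitted standardization state.
    """

    values: np.ndarray
    feature_index: list[tuple[int, str]]
    band_names: tuple[str, ...]
    log_applied: bool = False
    transform: FeatureTransform | None = None

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _band_power_kernels(
    bands: tuple[BandDef, ...], fs: float, n_pad: int, freq_step: float
) -> np.ndarray:
    """Mean squared-magnitude response per band on the rfft grid of the
    padded signal: rows are bands, columns positive-frequency bins."""
    freqs = np.arange(n_pad // 2 + 1) * (fs / n_pad)
    rows = []
    for b in bands:
        gains = []
        for f0 in band_frequencies(b, freq_step):
            sf = wavelet_sigma_f(f0)
            # power gain of the analytic (one-sided, sqrt(2)-scaled) kernel
            gains.append(2.0 * np.exp(-((freqs - f0) ** 2) / (sf**2)))
        rows.append(np.mean(gains, axis=0))
    return np.stack(rows)


def morlet_band_power(
    epochs: EpochSet,
    bands: tuple[BandDef, ...] = DEFAULT_BANDS,
    freq_step: float = 1.0,
) -> SpectralFeatureMatrix:
    """Raw (pre-log) mean band power per epoch, channel and band.

    Features are ordered channel-major: index = channel * n_bands + band.
    Deterministic: identical epochs give identical features.
    """
    nyquist = epochs.fs / 2.0
    for b in bands:
        if b.f_hi > nyquist:
            raise SpectralError(
                f"band {b.name!r} upper edge {b.f_hi} Hz exceeds Nyquist "
                f"({nyquist} Hz)"
            )
    n_ep, n_ch, n_samp = epochs.data.shape
    n_pad = 3 * n_samp
    kernels = _band_power_kernels(bands, epochs.fs, n_pad, freq_step)
    n_bands = len(bands)

    values = np.zeros((n_ep, n_ch, n_bands), dtype=np.float64)
    # Parseval: mean_t |y|^2 = (1/N^2) sum_k |X_k W_k|^2; for a real signal
    # and one-sided kernels the rfft bins 1..N/2-1 each stand for a single
    # (positive-frequency) complex bin of the full transform.
    for start in range(0, n_ep, _CHUNK):
        stop = min(start + _CHUNK, n_ep)
        x = epochs.data[start:stop].astype(np.float32)
        xp = np.concatenate([x[:, :, ::-1], x, x[:, :, ::-1]], axis=-1)
        X = sfft.rfft(xp, axis=-1)
        P = (X.real.astype(np.float64) ** 2 + X.imag.astype(np.float64) ** 2)
        values[start:stop] = P @ kernels.T / (n_pad**2)

    feature_index = [(c, b.name) for c in range(n_ch) for b in bands]
    return SpectralFeatureMatrix(
        values=values.reshape(n_ep, n_ch * n_bands),
        feature_index=feature_index,
        band_names=tuple(b.name for b in bands),
    )


def log_and_standardize(
    raw: SpectralFeatureMatrix,
    fit_on: np.ndarray | None = None,
) -> SpectralFeatureMatrix:
    """log10(x + eps), then per-feature z-scoring fitted on ``fit_on``.

    ``fit_on`` is a boolean epoch mask selecting the training epochs the
    mean/SD are estimated from (all epochs when None); the fitted state is
    stored for reuse on validation epochs via :func:`apply_transform`, so
    no validation statistics leak into the transform.
    """
    if raw.log_applied:
        raise SpectralError("features are already log-standardized")
    logged = np.log10(raw.values + LOG_EPS)
    if fit_on is None:
        fit_on = np.ones(logged.shape[0], dtype=bool)
    fit_on = np.asarray(fit_on, dtype=bool)
    if fit_on.sum() == 0:
        raise SpectralError("fit_on selects no epochs")
    mean = logged[fit_on].mean(axis=0)
    sd = logged[fit_on].std(axis=0, ddof=0)
    zero = sd == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} features have zero SD on the fit epochs; "
            "their SD is floored to 1",
            UserWarning,
            stacklevel=2,
        )
        sd = np.where(zero, 1.0, sd)
    transform = FeatureTransform(mean=mean, sd=sd)
    return SpectralFeatureMatrix(
        values=(logged - mean) / sd,
        feature_index=list(raw.feature_index),
        band_names=raw.band_names,
        log_applied=True,
        transform=transform,
    )


def apply_transform(
    raw: SpectralFeatureMatrix, transform: FeatureTransform
) -> SpectralFeatureMatrix:
    """Apply a previously fitted log + z-scoring state to new epochs."""
    if raw.log_applied:
        raise SpectralError("features are already log-standardized")
    logged = np.log10(raw.values + transform.log_eps)
    return SpectralFeatureMatrix(
        values=(logged - transform.mean) / transform.sd,
        feature_index=list(raw.feature_index),
        band_names=raw.band_names,
        log_applied=True,
        transform=transform,
    )
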