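"""Epoch segmentation and wavelet band-power features.

A single-channel EEG record is cut into non-overlapping 30-s epochs, and each
epoch is summarized by the relative power in four stage-associated frequency
bands: Wake 35–50 Hz, REM 20–30 Hz, Light 10.15–15.75 Hz and Deep 1–3 Hz.
Band filtering uses a complex Morlet continuous wavelet transform evaluated on
a grid of frequencies spanning each band; an order-4 zero-phase Butterworth
band-pass estimator is provided as an independent cross-check. Powers are
normalized per epoch to sum to one, so each feature row lives on the
four-dimensional probability simplex — the scale the staging model's 0.7/0.1
initial emission means assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BandSet",
    "DEFAULT_BANDS",
    "segment_epochs",
    "BandPowerTransformer",
    "band_power_features",
    "bandpass_band_powers",
]


@dataclass(frozen=True)
class BandSet:
    """Ordered stage-band definitions, (name, low Hz, high Hz), Stage order."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.bands) != 4:
            raise ValueError("exactly four stage bands are required")
        for name, lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ValueError(f"band {name}: need 0 < low < high, got ({lo}, {hi})")

    @property
    def max_edge_hz(self) -> float:
        return max(hi for _, _, hi in self.bands)

    def frequency_grid(self, step_hz: float = 1.0) -> list[np.ndarray]:
        """Per band: integer-step frequencies inside the band plus its
        (possibly fractional) edges."""
        grids = []
        for _, lo, hi in self.bands:
            inner = np.arange(np.ceil(lo), np.floor(hi) + 0.5, step_hz)
            freqs = np.unique(np.concatenate([[lo], inner, [hi]]))
            grids.append(freqs[(freqs >= lo) & (freqs <= hi)])
        return grids


DEFAULT_BANDS = BandSet(
    (
        ("wake", 35.0, 50.0),
        ("rem", 20.0, 30.0),
        ("light", 10.15, 15.75),
        ("deep", 1.0, 3.0),
    )
)


def segment_epochs(signal, sampling_rate_hz: float, epoch_seconds: float = 30.0) -> np.ndarray:
    """Split a 1-D signal into non-overlapping equal epochs.

    Returns an ``(n_epochs, samples_per_epoch)`` array; a trailing partial
    epoch is dropped. Raises ``ValueError`` if the signal is shorter than one
    epoch.
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    x = np.asarray(signal, dtype=float).ravel()
    samples_per_epoch = int(round(sampling_rate_hz * epoch_seconds))
    n_epochs = x.size // samples_per_epoch
    if n_epochs < 1:
        raise ValueError(
            f"signal of {x.size} samples holds no complete "
            f"{epoch_seconds}-s epoch at {sampling_rate_hz} Hz"
        )
    return x[: n_epochs * samples_per_epoch].reshape(n_epochs, samples_per_epoch)


class BandPowerTransformer(TransformerMixin, BaseEstimator):
    """Relative band powers per epoch via complex Morlet wavelet filtering.

    Parameters
    ----------
    sampling_rate_hz : float
        Sampling rate of the epochs passed to :meth:`transform`. Must be at
        least twice the highest band edge.
    band_set : BandSet, optional
        Stage bands; defaults to the Wake/REM/Light/Deep set.
    wavelet : str, default "cmor2.0-1.0"
        Complex Morlet wavelet (bandwidth–center-frequency parametrization).
        The default bandwidth balances in-band selectivity against the time
        support of the 1-Hz wavelet relative to a 30-s epoch.
    freq_step_hz : float, default 0.5
        Spacing of the frequency grid inside each band.

    Epochs are reflect-padded by the longest wavelet's support before the
    transform so low-frequency band powers are not attenuated at epoch edges.
    The transform is stateless; ``fit`` only validates parameters.
    """

    def __init__(
        self,
        sampling_rate_hz: float = 100.0,
        band_set: BandSet | None = None,
        wavelet: str = "cmor2.0-1.0",
        freq_step_hz: float = 0.5,
    ) -> None:
        self.sampling_rate_hz = sampling_rate_hz
        self.band_set = band_set
        self.wavelet = wavelet
        self.freq_step_hz = freq_step_hz

    def _validate(self) -> BandSet:
        bands = self.band_set if self.band_set is not None else DEFAULT_BANDS
        if self.sampling_rate_hz < 2 * bands.max_edge_hz:
            raise ValueError(
                f"sampling rate {self.sampling_rate_hz} Hz is below twice the "
                f"highest band edge ({bands.max_edge_hz} Hz)"
            )
        return bands

    def fit(self, X=None, y=None):
        self._validate()
        self.n_features_in_ = 0 if X is None else np.atleast_2d(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Epochs ``(n_epochs, n_samples)`` -> relative powers ``(n_epochs, 4)``."""
        bands = self._validate()
        epochs = np.atleast_2d(np.asarray(X, dtype=float))
        n_epochs = epochs.shape[0]
        power = np.empty((n_epochs, 4))
        grids = bands.frequency_grid(self.freq_step_hz)
        # chunk epochs to bound CWT memory (n_scales x chunk x n_samples complex)
        chunk = max(1, int(2e6 // max(epochs.shape[1], 1)))
        for b, freqs in enumerate(grids):
            scales = pywt.frequency2scale(self.wavelet, freqs / self.sampling_rate_hz)
            # reflect-pad past the longest wavelet support so the slowest band
            # is not attenuated where the wavelet overhangs the epoch edge
            pad = min(int(np.ceil(8 * scales.max())), epochs.shape[1])
            # pywt's CWT differentiates the integrated wavelet, which imposes a
            # first-difference sinc^2 rolloff toward Nyquist; undo it so the
            # per-frequency response to flat-spectrum input is level
            rolloff = np.sinc(freqs / self.sampling_rate_hz) ** 2
            for start in range(0, n_epochs, chunk):
                seg = np.pad(epochs[start : start + chunk], ((0, 0), (pad, pad)),
                             mode="reflect")
                coef, _ = pywt.cwt(seg, scales, self.wavelet, axis=-1, method="fft")
                coef = coef[:, :, pad:-pad] if pad else coef
                psd = np.mean(np.abs(coef) ** 2, axis=2) / rolloff[:, None]
                # integrate the corrected spectral density over the band so
                # band power is comparable across unequal band widths
                power[start : start + chunk, b] = np.trapezoid(psd, freqs, axis=0)
        total = power.sum(axis=1, keepdims=True)
        if np.any(total <= 0):
            raise ValueError("epoch with zero total band power (constant signal?)")
        return power / total


def band_power_features(
    epochs,
    sampling_rate_hz: float,
    band_set: BandSet | None = None,
    **kwargs,
) -> np.ndarray:
    """Functional wrapper over :class:`BandPowerTransformer`."""
    tr = BandPowerTransformer(sampling_rate_hz=sampling_rate_hz, band_set=band_set, **kwargs)
    return tr.fit(epochs).transform(epochs)


def bandpass_band_powers(
    epochs, sampling_rate_hz: float, band_set: BandSet | None = None
) -> np.ndarray:
    """Relative band powers via order-4 zero-phase Butterworth filtering.

    Independent of the wavelet path; used as a cross-check estimator. Band
    edges at or above Nyquist are clipped just below it.
    """
    bands = band_set if band_set is not None else DEFAULT_BANDS
    if sampling_rate_hz < 2 * bands.max_edge_hz * 0.999:
        raise ValueError("sampling rate too low for the requested bands")
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    nyq = sampling_rate_hz / 2.0
    power = np.empty((epochs.shape[0], 4))
    for b, (_, lo, hi) in enumerate(bands.bands):
        hi_eff = min(hi, 0.99 * nyq)
        sos = sps.butter(4, [lo, hi_eff], btype="bandpass", fs=sampling_rate_hz, output="sos")
        filtered = sps.sosfiltfilt(sos, epochs, axis=-1)
        power[:, b] = np.mean(filtered**2, axis=-1)
    return power / power.sum(axis=1, keepdims=True)


def features_to_frame(features: np.ndarray):
    """Feature matrix -> DataFrame with epoch_index and p_<stage> columns."""
    import pandas as pd

    features = np.atleast_2d(features)
    cols = {f"p_{name.lower()}": features[:, i] for i, name in enumerate(
        ("wake", "rem", "light", "deep"))}
    df = pd.DataFrame(cols)
    df.insert(0, "epoch_index", np.arange(features.shape[0]))
    return df
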