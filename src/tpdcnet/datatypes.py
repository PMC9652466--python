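"""Core containers shared across the pipeline.

The pipeline's unit of exchange is the labelled multichannel time series
(:class:`ROITimeSeries`), the per-time-point MVAR coefficient array produced by
the Kalman estimators (:class:`TimeVaryingMVAR`), and the frequency-domain
objects derived from it (:class:`FrequencyTransfer`, :class:`PDCSpectrum`).
Tabular cohort data (subjects x directed-EC features) travels as plain pandas
DataFrames; see :mod:`tpdcnet.simulate` for the column conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TpdcError(Exception):
    """Base class for user-facing errors raised by this package."""


@dataclass
class ROITimeSeries:
    """A labelled multichannel signal with a sampling rate.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Real-valued samples; no missing values allowed.
    labels : list of str
        One name per channel (e.g. ROI names ``PFC, MC, BS, CB, SC`` or
        fNIRS probe names ``L, R``).
    sampling_rate : float
        Sampling frequency in Hz; must be positive.
    """

    data: np.ndarray
    labels: list[str]
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        if self.data.ndim != 2:
            raise TpdcError("time-series data must be 2-D (samples x channels)")
        if self.data.shape[1] < 2:
            raise TpdcError("a time series needs at least 2 channels")
        if len(self.labels) != self.data.shape[1]:
            raise TpdcError(
                f"{len(self.labels)} labels for {self.data.shape[1]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise TpdcError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            raise TpdcError("time series contains non-finite values")
        if not self.sampling_rate > 0:
            raise TpdcError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class TimeVaryingMVAR:
    """Per-time-point MVAR lag coefficients plus innovation covariance.

    ``coeffs[t, r, i, j]`` is the influence of channel ``j`` at lag ``r+1`` on
    channel ``i`` at time ``t``.  ``valid_range`` marks the half-open index
    interval ``[start, stop)`` after estimator burn-in inside which the
    coefficients are trusted; time averaging downstream uses only this range.
    """

    order: int
    coeffs: np.ndarray  # (T, p, N, N)
    innovation_cov: np.ndarray  # (N, N)
    sampling_rate: float
    labels: list[str]
    valid_range: tuple[int, int] = field(default=(0, 0))

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.innovation_cov = np.asarray(self.innovation_cov, dtype=float)
        T = self.coeffs.shape[0]
        if self.valid_range == (0, 0):
            self.valid_range = (0, T)
        lo, hi = self.valid_range
        if not (0 <= lo < hi <= T):
            raise TpdcError(f"invalid valid_range {self.valid_range} for T={T}")
        if self.coeffs.ndim != 4 or self.coeffs.shape[1] != self.order:
            raise TpdcError("coeffs must have shape (T, order, N, N)")
        if not np.isfinite(self.coeffs[lo:hi]).all():
            raise TpdcError("non-finite coefficients inside valid_range")
        if not np.allclose(self.innovation_cov, self.innovation_cov.T, atol=1e-8):
            raise TpdcError("innovation covariance must be symmetric")
        if np.linalg.eigvalsh(self.innovation_cov).min() < -1e-8:
            raise TpdcError("innovation covariance must be positive semi-definite")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]


@dataclass
class FrequencyTransfer:
    """Fourier-transformed MVAR coefficients Abar(t, f) = I - sum_r A_r(t) e^{-i 2 pi f r / fs}."""

    freqs: np.ndarray  # (F,)
    abar: np.ndarray  # (T_valid, F, N, N) complex
    sampling_rate: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.abar = np.asarray(self.abar, dtype=complex)
        if self.freqs.size == 0:
            raise TpdcError("frequency grid is empty")
        if self.abar.ndim != 4:
            raise TpdcError("abar must have shape (T, F, N, N)")


@dataclass
class PDCSpectrum:
    """Squared partial directed coherence over (time, frequency, target, source).

    ``values[t, f, i, j] = |pi_{i<-j}(f)|^2`` at time point ``t``.  Values lie
    in [0, 1] and, for every time, frequency and source channel j, the squared
    PDC sums to 1 over targets i (column normalisation per source).
    """

    values: np.ndarray  # (T, F, N, N)
    freqs: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.ndim != 4:
            raise TpdcError("PDC values must have shape (T, F, N, N)")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise TpdcError("squared PDC values must lie in [0, 1]")
        colsums = self.values.sum(axis=2)
        if not np.allclose(colsums, 1.0, atol=1e-10):
            raise TpdcError("squared PDC columns must sum to 1 per source")
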