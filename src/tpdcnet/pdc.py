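"""Partial directed coherence from time-varying MVAR coefficients.

The chain is: Fourier-transform the lag coefficients into
``Abar(t, f) = I - sum_r A_r(t) exp(-i 2 pi f r / fs)``, form the squared PDC

    |pi_{i<-j}(f)|^2 = |Abar_ij(f)|^2 / sum_k |Abar_kj(f)|^2,

then average over the frequency band of interest (0.009-0.08 Hz for the
hemodynamic signals handled here) and over all post-burn-in time points to
obtain one directed effective-connectivity (EC) matrix.

The ``I - A(f)`` convention is the standard PDC definition: with raw ``A``
alone the source column of a null (zero-coefficient) model would vanish and
the normalisation would be undefined, whereas ``Abar`` always carries the
identity on its diagonal term.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import FrequencyTransfer, PDCSpectrum, TimeVaryingMVAR, TpdcError
from .mvar import EKFConfig, dual_ekf_fit

logger = logging.getLogger(__name__)

#: Hemodynamic frequency band of interest (Hz).
DEFAULT_BAND: tuple[float, float] = (0.009, 0.08)
#: Default number of grid points on [0, fs/2].
DEFAULT_N_FREQS: int = 129


def default_freq_grid(fs: float, n_freqs: int = DEFAULT_N_FREQS) -> np.ndarray:
    """Evenly spaced frequency grid on [0, fs/2]."""
    return np.linspace(0.0, fs / 2.0, n_freqs)


def transfer_function(
    model: TimeVaryingMVAR,
    freqs: np.ndarray | None = None,
    fs: float | None = None,
) -> FrequencyTransfer:
    """Fourier-transform the MVAR coefficients over the model's valid range."""
    fs = fs if fs is not None else model.sampling_rate
    freqs = default_freq_grid(fs) if freqs is None else np.asarray(freqs, float)
    if freqs.size == 0:
        raise TpdcError("frequency grid is empty")
    if freqs.min() < 0 or freqs.max() > fs / 2 + 1e-12:
        raise TpdcError("frequencies must lie within [0, fs/2]")
    lo, hi = model.valid_range
    A = model.coeffs[lo:hi]  # (T, p, N, N)
    p = model.order
    N = model.n_channels
    lags = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * freqs[:, None] * lags[None, :] / fs)  # (F, p)
    abar = np.eye(N)[None, None] - np.einsum("fr,trij->tfij", phase, A)
    return FrequencyTransfer(
        freqs=freqs, abar=abar, sampling_rate=fs, labels=model.labels
    )


def pdc(tf: FrequencyTransfer) -> PDCSpectrum:
    """Squared PDC from the frequency transfer: column-normalised per source."""
    if not np.isfinite(tf.abar).all():
        raise TpdcError("transfer function contains non-finite values")
    num = np.abs(tf.abar) ** 2  # (T, F, N, N)
    denom = num.sum(axis=2)  # sum over targets k, per source column j
    if (denom <= 0).any():
        t, f, j = np.argwhere(denom <= 0)[0]
        raise TpdcError(
            f"all-zero source column j={j} at time {t}, frequency index {f}"
        )
    values = num / denom[:, :, None, :]
    return PDCSpectrum(values=values, freqs=tf.freqs, labels=tf.labels)


def band_average(
    spec: PDCSpectrum,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
) -> pd.DataFrame:
    """EC matrix: squared PDC averaged over the closed band and over time.

    Returns a labelled DataFrame with rows = targets, columns = sources; the
    number of in-band frequency bins used is recorded in ``attrs['n_bins']``.
    The diagonal is retained in the matrix but excluded from feature export
    (see :func:`ec_features`).
    """
    if f_hi < f_lo:
        raise TpdcError("band upper edge below lower edge")
    mask = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    n_bins = int(mask.sum())
    if n_bins == 0:
        raise TpdcError(
            f"band [{f_lo}, {f_hi}] Hz contains no grid frequencies "
            f"(grid spans [{spec.freqs.min():.4g}, {spec.freqs.max():.4g}] Hz)"
        )
    logger.debug("band average over %d bins in [%g, %g] Hz", n_bins, f_lo, f_hi)
    mat = spec.values[:, mask].mean(axis=(0, 1))
    out = pd.DataFrame(mat, index=list(spec.labels), columns=list(spec.labels))
    out.attrs["n_bins"] = n_bins
    out.attrs["band"] = (f_lo, f_hi)
    return out


def ec_features(ec_matrix: pd.DataFrame) -> pd.Series:
    """Flatten an EC matrix to the directed feature vector ``"SRC->DST"``.

    Ordering follows :func:`tpdcnet.simulate.feature_names` (source-major,
    diagonal excluded).
    """
    labels = list(ec_matrix.columns)
    values = {}
    for src in labels:
        for dst in labels:
            if src != dst:
                values[f"{src}->{dst}"] = float(ec_matrix.loc[dst, src])
    return pd.Series(values)


def tpdc(
    ts,
    order: int = 1,
    band: tuple[float, float] = DEFAULT_BAND,
    config: EKFConfig | None = None,
    freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full TPDC chain: dual EKF -> transfer function -> squared PDC -> band-averaged EC."""
    model = dual_ekf_fit(ts, order=order, config=config)
    tf = transfer_function(model, freqs=freqs)
    return band_average(pdc(tf), *band)
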