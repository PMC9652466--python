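"""MVAR coefficient estimation: stationary least squares and the dual EKF.

The time-resolved connectivity chain rests on per-time-point MVAR
coefficients.  Two estimators are provided in scikit-learn style:

* :class:`StationaryMVAR` — ordinary least-squares VAR(p) fit; serves as the
  oracle against which the tracking filter is validated, and as the source of
  information-criterion order selection.
* :class:`DualEKFMVAR` — the dual extended Kalman filter: a state filter for
  the signal and a weight filter for the stacked MVAR coefficients run
  forward in lock-step, each using the other's current estimate.  The weight
  filter follows a random walk whose process noise sets the tracking speed.

Both consume ``(n_samples, n_channels)`` arrays or :class:`ROITimeSeries`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import ROITimeSeries, TimeVaryingMVAR, TpdcError

logger = logging.getLogger(__name__)


def _as_array(ts: ROITimeSeries | np.ndarray) -> tuple[np.ndarray, list[str], float]:
    if isinstance(ts, ROITimeSeries):
        return ts.data, ts.labels, ts.sampling_rate
    x = np.asarray(ts, dtype=float)
    if x.ndim != 2:
        raise TpdcError("expected a 2-D samples x channels array")
    return x, [f"ch{i + 1}" for i in range(x.shape[1])], 1.0


def _lagged_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (Z, Y) with Z[t] = [x_{t-1}, ..., x_{t-p}] stacked, Y[t] = x_t."""
    T, N = x.shape
    Z = np.column_stack([x[p - 1 - r : T - 1 - r] for r in range(p)])
    return Z, x[p:]


class StationaryMVAR(BaseEstimator):
    """Least-squares VAR(p) fit with constant coefficients.

    Fitted attributes
    -----------------
    coeffs_ : ndarray (p, N, N)
        ``coeffs_[r, i, j]`` is the influence of channel j at lag r+1 on
        channel i.
    innovation_cov_ : ndarray (N, N)
        Residual covariance.
    coeff_se_ : ndarray (p, N, N)
        Large-sample standard errors of the coefficients.
    """

    def __init__(self, order: int = 1, demean: bool = True):
        self.order = order
        self.demean = demean

    def fit(self, X, y=None):
        x, labels, fs = _as_array(X)
        p, (T, N) = self.order, x.shape
        if p < 1:
            raise TpdcError("order must be >= 1")
        if T <= 10 * p * N:
            raise TpdcError("need more than 10 * order * n_channels samples")
        self.mean_ = x.mean(axis=0) if self.demean else np.zeros(N)
        xc = x - self.mean_
        Z, Y = _lagged_design(xc, p)
        rank = np.linalg.matrix_rank(Z)
        if rank < Z.shape[1]:
            raise TpdcError(
                f"singular fit: regressor matrix has rank {rank} < {Z.shape[1]}"
            )
        G = Z.T @ Z
        B = np.linalg.solve(G, Z.T @ Y)  # (pN, N), column i = coeffs for channel i
        resid = Y - Z @ B
        dof = max(Z.shape[0] - Z.shape[1], 1)
        self.innovation_cov_ = resid.T @ resid / dof
        Ginv_diag = np.diag(np.linalg.inv(G))
        se = np.sqrt(
            np.outer(Ginv_diag, np.diag(self.innovation_cov_))
        )  # (pN, N)
        # B[(r*N + j), i] -> coeffs_[r, i, j]
        self.coeffs_ = B.reshape(p, N, N).transpose(0, 2, 1)
        self.coeff_se_ = se.reshape(p, N, N).transpose(0, 2, 1)
        self.resid_ = resid
        self.labels_ = labels
        self.sampling_rate_ = fs
        self.n_samples_ = T
        return self

    def to_time_varying(self, n_time: int | None = None) -> TimeVaryingMVAR:
        """Replicate the constant fit per time point (oracle form)."""
        T = self.n_samples_ if n_time is None else n_time
        coeffs = np.broadcast_to(
            self.coeffs_, (T, self.order) + self.coeffs_.shape[1:]
        ).copy()
        return TimeVaryingMVAR(
            order=self.order,
            coeffs=coeffs,
            innovation_cov=self.innovation_cov_,
            sampling_rate=self.sampling_rate_,
            labels=self.labels_,
        )


def fit_stationary_mvar(ts: ROITimeSeries | np.ndarray, order: int) -> TimeVaryingMVAR:
    """Least-squares VAR(p) fit, replicated per time point."""
    est = StationaryMVAR(order=order).fit(ts)
    return est.to_time_varying()


def select_order(
    ts: ROITimeSeries | np.ndarray,
    max_order: int,
    criterion: str = "bic",
) -> int:
    """Pick the VAR order in 1..max_order minimising AIC or BIC.

    All candidate orders are fitted on the common effective sample (the first
    ``max_order`` rows are dropped for every candidate) so the criteria are
    comparable.  For a VAR(p) the per-equation parameter count is p N^2 and

        IC(p) = log det(Sigma_p) + penalty * p N^2 / T_eff

    with penalty 2 (AIC) or log T_eff (BIC).
    """
    x, _, _ = _as_array(ts)
    T, N = x.shape
    if max_order < 1:
        raise TpdcError("max_order must be >= 1")
    if T - max_order <= 10 * max_order * N:
        raise TpdcError("max_order too large for the sample size")
    crit = criterion.lower()
    if crit not in ("aic", "bic"):
        raise TpdcError("criterion must be 'AIC' or 'BIC'")
    xc = x - x.mean(axis=0)
    scores = {}
    T_eff = T - max_order
    for p in range(1, max_order + 1):
        Z = np.column_stack(
            [xc[max_order - 1 - r : T - 1 - r] for r in range(p)]
        )
        Y = xc[max_order:]
        B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        resid = Y - Z @ B
        sigma = resid.T @ resid / T_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise TpdcError(f"degenerate residual covariance at order {p}")
        penalty = 2.0 if crit == "aic" else np.log(T_eff)
        scores[p] = logdet + penalty * p * N * N / T_eff
    best = min(scores, key=scores.get)
    logger.debug("order selection (%s): %s -> %d", crit.upper(), scores, best)
    return best


@dataclass
class EKFConfig:
    """Tunable constants of the dual EKF (all logged at fit time).

    weight_process_noise
        Diagonal random-walk variance of the coefficient state; larger values
        track faster but with more variance.  Default 1e-4.
    obs_noise_scale
        State-filter measurement-noise variance as a fraction of each
        channel's sample variance; small values keep the filtered signal
        close to the observations.
    init_window
        Leading samples used for the stationary least-squares initialisation
        of the weight filter: max(5 p N, 100), capped at half the series.
    burn_in
        Samples excluded from ``valid_range``; ``None`` selects
        max(50, 5 p N) capped at a quarter of the series.
    divergence_bound
        Hard cap on the coefficient magnitude; exceeding it raises.
    """

    weight_process_noise: float = 1e-4
    obs_noise_scale: float = 1e-2
    init_window: int | None = None
    burn_in: int | None = None
    divergence_bound: float = 1e3


class DualEKFMVAR(BaseEstimator):
    """Dual extended Kalman filter for time-varying MVAR coefficients.

    Two coupled filters run forward over the series: a state filter for the
    stacked signal (dimension p N, companion dynamics built from the current
    weight estimate) and a weight filter for the stacked MVAR coefficients
    (dimension p N^2, random-walk dynamics, measurement linearised around the
    current filtered state).  With a diagonal measurement-noise model the
    weight filter decouples into N independent filters of dimension p N,
    which is how it is implemented.

    Fitted attributes
    -----------------
    coeffs_ : ndarray (T, p, N, N)
        Per-time-point coefficient estimates (zeros before lag p).
    innovation_cov_ : ndarray (N, N)
        Covariance of one-step prediction errors over the valid range.
    valid_range_ : (int, int)
        Half-open index range after burn-in.
    """

    def __init__(
        self,
        order: int = 1,
        weight_process_noise: float = 1e-4,
        obs_noise_scale: float = 1e-2,
        init_window: int | None = None,
        burn_in: int | None = None,
        divergence_bound: float = 1e3,
    ):
        self.order = order
        self.weight_process_noise = weight_process_noise
        self.obs_noise_scale = obs_noise_scale
        self.init_window = init_window
        self.burn_in = burn_in
        self.divergence_bound = divergence_bound

    def fit(self, X, y=None):
        x, labels, fs = _as_array(X)
        T, N = x.shape
        p = self.order
        if p < 1:
            raise TpdcError("order must be >= 1")
        if T <= 20 * p * N:
            raise TpdcError("need more than 20 * order * n_channels samples")
        if not np.isfinite(x).all():
            raise TpdcError("input contains non-finite values")
        var0 = x.var(axis=0)
        if (var0 <= 1e-15).any():
            bad = int(np.argmin(var0))
            raise TpdcError(
                f"channel {labels[bad]!r} has zero variance; cannot estimate MVAR"
            )

        self.mean_ = x.mean(axis=0)
        xc = x - self.mean_
        d = p * N

        init_n = self.init_window or min(max(5 * p * N, 100), T // 2)
        init_fit = StationaryMVAR(order=p, demean=False).fit(xc[:init_n])
        # weight matrix W: column i holds channel i's pN coefficients
        W = init_fit.coeffs_.transpose(0, 2, 1).reshape(d, N)
        rvar = np.clip(np.diag(init_fit.innovation_cov_), 1e-10, None)

        qw = self.weight_process_noise
        Pw = np.repeat(np.eye(d)[None] * 1e-2, N, axis=0)
        obs_var = np.clip(var0 * self.obs_noise_scale, 1e-12, None)

        # state filter (companion form)
        z = np.concatenate([xc[p - 1 - r] for r in range(p)])
        Pz = np.eye(d)
        Qz = np.zeros((d, d))
        Qz[:N, :N] = np.diag(rvar)
        Rz = np.diag(obs_var)
        IN = np.eye(N)

        coeffs = np.zeros((T, p, N, N))
        resid = np.zeros((T, N))
        bound = self.divergence_bound
        for t in range(p, T):
            y_t = xc[t]
            phi = z  # lagged filtered signal, the weight-filter regressor
            # --- weight filter: N decoupled scalar-measurement updates
            for i in range(N):
                Pi = Pw[i]
                Pi.flat[:: d + 1] += qw  # predict: P += qw I
                Pphi = Pi @ phi
                s = phi @ Pphi + rvar[i]
                k = Pphi / s
                innov = y_t[i] - phi @ W[:, i]
                resid[t, i] = innov
                W[:, i] += k * innov
                Pw[i] = Pi - np.outer(k, Pphi)
            if np.abs(W).max() > bound:
                raise TpdcError(
                    f"dual EKF diverged at time index {t}: "
                    f"coefficient magnitude exceeds {bound}"
                )
            coeffs[t] = W.reshape(p, N, N).transpose(0, 2, 1)
            # --- state filter: predict with companion dynamics from current W
            F = np.zeros((d, d))
            F[:N] = W.T
            if p > 1:
                F[N:, :-N] = np.eye(d - N)
            zp = F @ z
            Pzp = F @ Pz @ F.T + Qz
            S = Pzp[:N, :N] + Rz
            K = np.linalg.solve(S, Pzp[:N]).T
            z = zp + K @ (y_t - zp[:N])
            Pz = Pzp - K @ Pzp[:N]
            Pz = 0.5 * (Pz + Pz.T)

        burn = self.burn_in
        if burn is None:
            burn = min(max(50, 5 * p * N), T // 4)
        lo = max(burn, p)
        self.valid_range_ = (lo, T)
        r = resid[lo:]
        self.innovation_cov_ = r.T @ r / r.shape[0]
        self.coeffs_ = coeffs
        self.labels_ = labels
        self.sampling_rate_ = fs
        logger.info(
            "dual EKF: T=%d N=%d p=%d qw=%.2e obs_noise_scale=%.2e "
            "init_window=%d burn_in=%d",
            T, N, p, qw, self.obs_noise_scale, init_n, lo,
        )
        return self

    def to_time_varying(self) -> TimeVaryingMVAR:
        return TimeVaryingMVAR(
            order=self.order,
            coeffs=self.coeffs_,
            innovation_cov=self.innovation_cov_,
            sampling_rate=self.sampling_rate_,
            labels=self.labels_,
            valid_range=self.valid_range_,
        )


def dual_ekf_fit(
    ts: ROITimeSeries | np.ndarray,
    order: int,
    config: EKFConfig | None = None,
) -> TimeVaryingMVAR:
    """Fit the dual EKF and return the time-varying MVAR coefficients."""
    cfg = config or EKFConfig()
    est = DualEKFMVAR(
        order=order,
        weight_process_noise=cfg.weight_process_noise,
        obs_noise_scale=cfg.obs_noise_scale,
        init_window=cfg.init_window,
        burn_in=cfg.burn_in,
        divergence_bound=cfg.divergence_bound,
    ).fit(ts)
    return est.to_time_varying()
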