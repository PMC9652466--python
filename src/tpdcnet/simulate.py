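"""Synthetic ground-truth generators.

Two families of synthetic data drive the test harness and the demo pipeline:

* time-varying MVAR signals with known lag-coefficient trajectories, standing
  in for extracted ROI time series (slow "fMRI-like" 5-channel series at
  1/1.7 Hz, and "fNIRS-like" 2-channel 10 Hz walking trials);
* two-group (PD / HC), two-session (baseline / follow-up) cohorts of 20
  directed effective-connectivity features among five ROIs, with planted
  group and session effects and a response generated from a known feature
  subset.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .datatypes import ROITimeSeries, TpdcError

logger = logging.getLogger(__name__)

#: Canonical five large-scale ROI labels: prefrontal cortex, motor cortex,
#: brainstem, cerebellum, subcortical region.
ROI_LABELS: tuple[str, ...] = ("PFC", "MC", "BS", "CB", "SC")

#: fMRI-like sampling rate (TR = 1.7 s).
FMRI_SAMPLING_RATE: float = 1.0 / 1.7
#: fNIRS-like sampling rate.
FNIRS_SAMPLING_RATE: float = 10.0


def feature_names(labels: Sequence[str] = ROI_LABELS) -> list[str]:
    """Directed EC feature names ``"SRC->DST"`` over all ordered label pairs.

    Five ROI labels yield the canonical 5 x 4 = 20 directed features
    (diagonal pairs excluded).
    """
    return [f"{src}->{dst}" for src in labels for dst in labels if dst != src]


CoeffFn = Callable[[int], np.ndarray]


def constant_coeff_fn(matrices: np.ndarray) -> CoeffFn:
    """Coefficient trajectory that is constant in time.

    ``matrices`` has shape (p, N, N); a single (N, N) matrix is promoted to
    order p=1.
    """
    A = np.asarray(matrices, dtype=float)
    if A.ndim == 2:
        A = A[None]
    return lambda t: A


def step_coeff_fn(
    before: np.ndarray, after: np.ndarray, change_point: int
) -> CoeffFn:
    """Piecewise-constant trajectory: ``before`` for t < change_point, else ``after``."""
    B = np.asarray(before, dtype=float)
    Af = np.asarray(after, dtype=float)
    if B.ndim == 2:
        B = B[None]
    if Af.ndim == 2:
        Af = Af[None]
    if B.shape != Af.shape:
        raise TpdcError("before/after coefficient shapes differ")
    return lambda t: B if t < change_point else Af


def companion_spectral_radius(lag_matrices: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix; < 1 means stable."""
    A = np.asarray(lag_matrices, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, N, _ = A.shape
    comp = np.zeros((p * N, p * N))
    comp[:N] = A.transpose(1, 0, 2).reshape(N, p * N)
    if p > 1:
        comp[N:, :-N] = np.eye((p - 1) * N)
    return float(np.abs(np.linalg.eigvals(comp)).max())


@dataclass
class MVARSpec:
    """Specification of a (possibly time-varying) MVAR generative process.

    Parameters
    ----------
    n_channels, order : int
        Process dimension N and lag order p.
    coeff_fn : callable
        Map from output time index t (0-based) to the (p, N, N) lag matrices.
    noise_cov : ndarray (N, N)
        Innovation covariance; must be symmetric positive definite.
    sampling_rate : float
        Hz, attached to the emitted series.
    n_samples : int
        Output length after burn-in.
    post_smoothing : float, optional
        Width (seconds) of a causal gamma-shaped FIR kernel applied after
        generation to mimic hemodynamic smoothing; ``None`` disables it.
    labels : sequence of str, optional
        Channel names; defaults to ``ch1..chN``.
    """

    n_channels: int
    order: int
    coeff_fn: CoeffFn
    noise_cov: np.ndarray
    sampling_rate: float
    n_samples: int
    post_smoothing: float | None = None
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        N = self.n_channels
        if self.noise_cov.shape != (N, N):
            raise TpdcError("noise_cov must be N x N")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise TpdcError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() <= 0:
            raise TpdcError("noise_cov must be positive definite")
        if self.n_samples <= 10 * self.order * N:
            raise TpdcError("n_samples must exceed 10 * order * n_channels")
        if self.labels is None:
            self.labels = [f"ch{i + 1}" for i in range(N)]

    @property
    def burn_in(self) -> int:
        # discard initial-condition transients; the generative model has no
        # stated initialisation, so start from zeros and drop the transient
        return max(200, 10 * self.order)


def simulate_mvar(spec: MVARSpec, seed: int) -> ROITimeSeries:
    """Draw one realisation of the MVAR process defined by ``spec``.

    The first ``max(200, 10 p)`` samples are discarded as burn-in (the
    coefficient trajectory is held at its t=0 value during burn-in).  Raises
    if any requested time point has an unstable coefficient matrix, naming
    the first unstable index.
    """
    rng = np.random.default_rng(seed)
    N, p = spec.n_channels, spec.order
    burn = spec.burn_in
    T = spec.n_samples + burn

    # stability guard over every emitted time point (trajectory assumed
    # piecewise-smooth: checking each index is cheap at these sizes)
    for t in range(spec.n_samples):
        A = np.asarray(spec.coeff_fn(t), dtype=float)
        if A.ndim == 2:
            A = A[None]
        if A.shape != (p, N, N):
            raise TpdcError(f"coeff_fn(t={t}) returned shape {A.shape}")
        rho = companion_spectral_radius(A)
        if rho >= 1.0:
            raise TpdcError(
                f"unstable coefficient trajectory at time index {t} "
                f"(companion spectral radius {rho:.4f} >= 1)"
            )

    chol = np.linalg.cholesky(spec.noise_cov)
    innov = rng.standard_normal((T, N)) @ chol.T
    x = np.zeros((T, N))
    for t in range(T):
        A = np.asarray(spec.coeff_fn(max(t - burn, 0)), dtype=float)
        if A.ndim == 2:
            A = A[None]
        acc = innov[t].copy()
        for r in range(min(p, t)):
            acc += A[r] @ x[t - 1 - r]
        x[t] = acc
    out = x[burn:]
    if not np.isfinite(out).all():
        raise TpdcError("simulated series overflowed despite stability check")

    if spec.post_smoothing is not None:
        out = _gamma_smooth(out, spec.post_smoothing, spec.sampling_rate)

    return ROITimeSeries(out, list(spec.labels), spec.sampling_rate)


def _gamma_smooth(x: np.ndarray, width_s: float, fs: float) -> np.ndarray:
    """Causal gamma-shaped FIR smoothing (shape 2, scale width/2), unit gain."""
    if width_s <= 0:
        raise TpdcError("post_smoothing width must be positive")
    scale = width_s / 2.0
    t = np.arange(0, 5 * width_s + 1.0 / fs, 1.0 / fs)
    kernel = t * np.exp(-t / scale)
    kernel /= kernel.sum()
    return _signal.lfilter(kernel, [1.0], x, axis=0)


@dataclass
class CohortSpec:
    """Specification of a synthetic two-group, two-session EC cohort.

    Each subject carries 20 directed EC features in [0, 1].  A subject's
    latent feature level is drawn once (between-subject variation) and
    re-observed at each session with smaller within-subject noise, so paired
    session contrasts behave like repeated measures.  Group effects shift the
    PD group, session effects shift the follow-up session; values are clipped
    to [0, 1] after effects are applied.  The response column is a linear
    combination of the ``true_subset`` features plus Gaussian noise.
    """

    n_per_group: int = 19
    roi_labels: Sequence[str] = ROI_LABELS
    group_effects: Mapping[str, float] = field(default_factory=dict)
    session_effects: Mapping[str, float] = field(default_factory=dict)
    true_subset: Sequence[str] = ()
    response_coeffs: Sequence[float] = ()
    noise_sd: float = 0.0
    seed: int = 0
    base_mean: float = 0.35
    between_sd: float = 0.12
    within_sd: float = 0.05

    def __post_init__(self) -> None:
        self.features = feature_names(self.roi_labels)
        if len(self.roi_labels) == 5 and len(self.features) != 20:
            raise TpdcError("5 ROI labels must yield exactly 20 directed features")
        unknown = set(self.true_subset) - set(self.features)
        if unknown:
            raise TpdcError(f"true_subset not among feature names: {sorted(unknown)}")
        unknown = (set(self.group_effects) | set(self.session_effects)) - set(
            self.features
        )
        if unknown:
            raise TpdcError(f"effects reference unknown features: {sorted(unknown)}")
        if self.noise_sd < 0:
            raise TpdcError("noise_sd must be non-negative")
        if len(self.response_coeffs) not in (0, len(self.true_subset)):
            raise TpdcError("response_coeffs must match true_subset length")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the cohort table: one row per subject x session.

    Columns: ``subject_id``, ``group`` (PD/HC), ``session``
    (baseline/follow-up), the 20 feature columns, and ``response``.
    """
    rng = np.random.default_rng(spec.seed)
    feats = spec.features
    m = len(feats)
    g_shift = np.array([spec.group_effects.get(f, 0.0) for f in feats])
    s_shift = np.array([spec.session_effects.get(f, 0.0) for f in feats])
    coeffs = np.array(
        list(spec.response_coeffs)
        if len(spec.response_coeffs)
        else [0.0] * len(spec.true_subset)
    )
    true_idx = [feats.index(f) for f in spec.true_subset]

    rows = []
    n_clipped = 0
    n_values = 0
    for group in ("PD", "HC"):
        latent = spec.base_mean + spec.between_sd * rng.standard_normal(
            (spec.n_per_group, m)
        )
        if group == "PD":
            latent = latent + g_shift
        for s_i, session in enumerate(("baseline", "follow-up")):
            obs = latent + spec.within_sd * rng.standard_normal(latent.shape)
            if session == "follow-up":
                obs = obs + s_shift
            clipped = np.clip(obs, 0.0, 1.0)
            n_clipped += int((clipped != obs).sum())
            n_values += obs.size
            resp = clipped[:, true_idx] @ coeffs if true_idx else np.zeros(
                spec.n_per_group
            )
            resp = resp + spec.noise_sd * rng.standard_normal(spec.n_per_group)
            for k in range(spec.n_per_group):
                sid = f"{group}{k + 1:02d}"
                rows.append(
                    {"subject_id": sid, "group": group, "session": session}
                    | dict(zip(feats, clipped[k]))
                    | {"response": resp[k]}
                )
    if n_values and n_clipped / n_values > 0.5:
        logger.warning(
            "effects pushed %.0f%% of EC values outside [0, 1]; they were clipped",
            100 * n_clipped / n_values,
        )
    return pd.DataFrame(rows)


def fmri_like_spec(
    coupling: np.ndarray | None = None,
    n_samples: int = 266,
    noise_scale: float = 1.0,
) -> MVARSpec:
    """A 5-channel resting-state-like MVAR spec (slow sampling, TR = 1.7 s).

    ``coupling`` is a (5, 5) lag-1 matrix; default is a weakly coupled stable
    network with 0.4 self-decay and a few directed influences.
    """
    if coupling is None:
        coupling = 0.4 * np.eye(5)
        coupling[1, 0] = 0.3  # PFC -> MC
        coupling[4, 3] = 0.25  # CB -> SC
        coupling[1, 4] = 0.2  # SC -> MC
    coupling = np.asarray(coupling, dtype=float)
    return MVARSpec(
        n_channels=5,
        order=1,
        coeff_fn=constant_coeff_fn(coupling),
        noise_cov=noise_scale * np.eye(5),
        sampling_rate=FMRI_SAMPLING_RATE,
        n_samples=n_samples,
        labels=ROI_LABELS,
    )


def fnirs_like_spec(
    left_to_right: float = 0.3,
    n_samples: int = 300,
    self_decay: float = 0.5,
) -> MVARSpec:
    """A 2-channel walking-trial-like MVAR spec (10 Hz, left/right prefrontal)."""
    A = np.array([[self_decay, 0.0], [left_to_right, self_decay]])
    return MVARSpec(
        n_channels=2,
        order=1,
        coeff_fn=constant_coeff_fn(A),
        noise_cov=np.eye(2),
        sampling_rate=FNIRS_SAMPLING_RATE,
        n_samples=n_samples,
        labels=["L", "R"],
    )
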