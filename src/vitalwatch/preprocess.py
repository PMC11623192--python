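"""Kalman filtering, RTS fixed-interval smoothing, error bands, normalization.

Linear-Gaussian state-space model

    y[k+1] = Phi y[k] + C u[k] + w[k],   w ~ N(0, Q)
    x[k]   = K y[k] + v[k],              v ~ N(0, R)

The filter alternates time updates (predict) and measurement updates
(correct); steps with a missing observation receive the time update only,
so irregular or infrequent measurements are handled by repeating time
updates across gaps.  The Rauch–Tung–Striebel backward pass refines every
filtered estimate using the whole record.  Error bands are mean ± m·SD
(m = 2 approximates a 95% interval under the Gaussian assumption).
Contrast normalization rescales each channel to a target mean/variance
(z-score at the default targets 0/1, population-variance convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .frames import SensorFrame, ValidationError

__all__ = [
    "StateSpaceModel",
    "StateEstimate",
    "SmoothedEstimate",
    "NumericalError",
    "kalman_filter",
    "rts_smooth",
    "error_band",
    "normalize",
    "local_level_model",
    "local_linear_trend_model",
    "smooth_frame",
]


class NumericalError(RuntimeError):
    """Raised when a covariance becomes singular or indefinite at some step."""


def _sym(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a.T)


def _check_psd(name: str, a: np.ndarray, tol: float = 1e-9) -> None:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if a.shape[0] != a.shape[1]:
        raise ValidationError(f"{name} must be square, got {a.shape}")
    if not np.allclose(a, a.T, atol=tol):
        raise ValidationError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(_sym(a))
    if w.min() < -tol:
        raise ValidationError(f"{name} must be positive semidefinite (min eig {w.min():.3g})")


@dataclass
class StateSpaceModel:
    """Matrices of the linear-Gaussian model; dimensions are validated."""

    transition: np.ndarray            # Phi, state x state
    measurement: np.ndarray           # K,   obs x state
    process_cov: np.ndarray           # Q,   state x state
    measurement_cov: np.ndarray       # R,   obs x obs
    initial_mean: np.ndarray
    initial_cov: np.ndarray
    input_map: np.ndarray | None = None   # C, state x input (optional)

    def __post_init__(self) -> None:
        self.transition = np.atleast_2d(np.asarray(self.transition, dtype=float))
        self.measurement = np.atleast_2d(np.asarray(self.measurement, dtype=float))
        self.process_cov = np.atleast_2d(np.asarray(self.process_cov, dtype=float))
        self.measurement_cov = np.atleast_2d(np.asarray(self.measurement_cov, dtype=float))
        self.initial_mean = np.atleast_1d(np.asarray(self.initial_mean, dtype=float))
        self.initial_cov = np.atleast_2d(np.asarray(self.initial_cov, dtype=float))
        if self.input_map is not None:
            self.input_map = np.atleast_2d(np.asarray(self.input_map, dtype=float))
        s = self.transition.shape[0]
        if self.transition.shape != (s, s):
            raise ValidationError("transition must be square")
        if self.measurement.shape[1] != s:
            raise ValidationError("measurement matrix column count must match state dim")
        if self.initial_mean.shape != (s,):
            raise ValidationError("initial_mean dimension mismatch")
        _check_psd("process_cov", self.process_cov)
        _check_psd("measurement_cov", self.measurement_cov)
        _check_psd("initial_cov", self.initial_cov)
        if self.process_cov.shape != (s, s) or self.initial_cov.shape != (s, s):
            raise ValidationError("covariance dimension mismatch with state")
        m = self.measurement.shape[0]
        if self.measurement_cov.shape != (m, m):
            raise ValidationError("measurement_cov dimension mismatch with measurement")

    @property
    def state_dim(self) -> int:
        return self.transition.shape[0]

    @property
    def obs_dim(self) -> int:
        return self.measurement.shape[0]


@dataclass
class StateEstimate:
    """Per-step prior/posterior means and covariances plus Kalman gains."""

    prior_means: np.ndarray       # T x s
    prior_covs: np.ndarray        # T x s x s
    posterior_means: np.ndarray   # T x s
    posterior_covs: np.ndarray    # T x s x s
    gains: np.ndarray             # T x s x m (zero rows at unmeasured steps)
    timestamps: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.posterior_means)


@dataclass
class SmoothedEstimate:
    means: np.ndarray             # T x s
    covs: np.ndarray              # T x s x s
    smoother_gains: np.ndarray    # (T-1) x s x s
    timestamps: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.means)


def _as_obs_matrix(observations, obs_dim: int) -> np.ndarray:
    x = np.asarray(observations, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] != obs_dim:
        raise ValidationError(f"observations have {x.shape[1]} columns, model expects {obs_dim}")
    return x


def kalman_filter(
    observations,
    model: StateSpaceModel,
    inputs=None,
) -> StateEstimate:
    """Run the forward filter over a possibly-missing observation sequence.

    ``observations`` is a (T,) or (T, m) array; ``NaN`` entries mark missing
    components and the measurement update uses only the observed rows of the
    measurement matrix.  Steps with no observed component are pure time
    updates, leaving posterior equal to prior.
    """
    x = _as_obs_matrix(observations, model.obs_dim)
    T = x.shape[0]
    if T < 1:
        raise ValidationError("at least one step is required")
    s, m = model.state_dim, model.obs_dim
    u = None
    if inputs is not None and model.input_map is not None:
        u = np.atleast_2d(np.asarray(inputs, dtype=float))
        if u.shape[0] != T:
            raise ValidationError("inputs must have one row per step")

    Phi, K, Q, R = model.transition, model.measurement, model.process_cov, model.measurement_cov
    prior_means = np.zeros((T, s))
    prior_covs = np.zeros((T, s, s))
    post_means = np.zeros((T, s))
    post_covs = np.zeros((T, s, s))
    gains = np.zeros((T, s, m))

    mean = model.initial_mean.copy()
    cov = model.initial_cov.copy()
    eye = np.eye(s)
    for k in range(T):
        if k > 0:
            # time update
            mean = Phi @ mean
            if u is not None:
                mean = mean + model.input_map @ u[k - 1]
            cov = _sym(Phi @ cov @ Phi.T + Q)
        prior_means[k] = mean
        prior_covs[k] = cov
        observed = np.isfinite(x[k])
        if observed.any():
            Ko = K[observed]
            Ro = R[np.ix_(observed, observed)]
            innov_cov = Ko @ cov @ Ko.T + Ro
            try:
                innov_cov_inv = np.linalg.inv(innov_cov)
            except np.linalg.LinAlgError as exc:
                raise NumericalError(f"singular innovation covariance at step {k}") from exc
            A = cov @ Ko.T @ innov_cov_inv
            innov = x[k][observed] - Ko @ mean
            mean = mean + A @ innov
            cov = _sym((eye - A @ Ko) @ cov)
            gains[k][:, observed] = A
        post_means[k] = mean
        post_covs[k] = cov
    return StateEstimate(prior_means, prior_covs, post_means, post_covs, gains)


def rts_smooth(filtered: StateEstimate, model: StateSpaceModel) -> SmoothedEstimate:
    """Rauch–Tung–Striebel fixed-interval backward pass.

    Smoother gain B[k] = P_post[k] Phi' P_prior[k+1]^{-1}; the final step is
    copied from the filter.  Smoothed variances never exceed filtered ones.
    """
    T = len(filtered)
    if T < 1:
        raise ValidationError("filtered sequence must be non-empty")
    s = model.state_dim
    Phi = model.transition
    means = np.zeros((T, s))
    covs = np.zeros((T, s, s))
    Bs = np.zeros((max(T - 1, 0), s, s))
    means[-1] = filtered.posterior_means[-1]
    covs[-1] = filtered.posterior_covs[-1]
    for k in range(T - 2, -1, -1):
        prior_next = filtered.prior_covs[k + 1]
        try:
            prior_next_inv = np.linalg.inv(prior_next)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular prior covariance at step {k + 1}") from exc
        B = filtered.posterior_covs[k] @ Phi.T @ prior_next_inv
        means[k] = filtered.posterior_means[k] + B @ (means[k + 1] - filtered.prior_means[k + 1])
        covs[k] = _sym(
            filtered.posterior_covs[k] + B @ (covs[k + 1] - prior_next) @ B.T
        )
        Bs[k] = B
    return SmoothedEstimate(means, covs, Bs, filtered.timestamps)


def error_band(
    est: StateEstimate | SmoothedEstimate,
    multiple: float = 2.0,
    component: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean ± multiple·SD band for one state component."""
    if multiple <= 0:
        raise ValidationError("multiple must be > 0")
    if isinstance(est, StateEstimate):
        means, covs = est.posterior_means, est.posterior_covs
    else:
        means, covs = est.means, est.covs
    s = means.shape[1]
    if not (0 <= component < s):
        raise ValidationError(f"component {component} out of range for state dim {s}")
    var = covs[:, component, component]
    if np.any(var < -1e-9):
        raise NumericalError("negative variance encountered in error band")
    sd = np.sqrt(np.clip(var, 0.0, None))
    mid = means[:, component]
    return mid - multiple * sd, mid + multiple * sd


def normalize(
    frame: SensorFrame,
    target_mean: float = 0.0,
    target_var: float = 1.0,
) -> SensorFrame:
    """Contrast-stretching normalization to a target mean and variance.

    Per channel the signed form  target_mean ± sqrt(target_var·(x−m)²/v)
    (sign of x−m) is applied, with m and v the channel's mean and
    *population* variance (divisor = count) over non-missing samples.  With
    the default targets this is the z-score and the output is idempotent.
    """
    if target_var < 0:
        raise ValidationError("target_var must be >= 0")
    out = frame.copy()
    for ch in out.channels:
        col = out.data[ch].to_numpy(dtype=float)
        finite = np.isfinite(col)
        if finite.sum() < 2:
            raise ValidationError(f"channel {ch!r} needs >= 2 non-missing values")
        m = col[finite].mean()
        v = np.mean((col[finite] - m) ** 2)
        if v <= 0:
            raise ValidationError(f"channel {ch!r} has zero variance; cannot normalize")
        centered = col - m
        scaled = target_mean + np.sign(centered) * np.sqrt(target_var * centered**2 / v)
        out.data[ch] = scaled
    return out


# ------------------------------------------------------ default channel model


def local_level_model(
    process_var: float,
    measurement_var: float,
    initial_mean: float = 0.0,
    initial_var: float = 1.0,
) -> StateSpaceModel:
    """1-D random-walk level model (the smallest useful filter)."""
    return StateSpaceModel(
        transition=[[1.0]],
        measurement=[[1.0]],
        process_cov=[[process_var]],
        measurement_cov=[[measurement_var]],
        initial_mean=[initial_mean],
        initial_cov=[[initial_var]],
    )


def local_linear_trend_model(
    dt: float,
    process_var: float,
    measurement_var: float,
    initial_mean=(0.0, 0.0),
    initial_var: float = 1e4,
) -> StateSpaceModel:
    """Level + slope model; the default per-channel smoother.

    The process covariance is the continuous-time integrated-noise form
    scaled by the elapsed ``dt`` so irregular gaps can be handled by
    rebuilding Phi and Q per interval.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    q = float(process_var)
    Phi = [[1.0, dt], [0.0, 1.0]]
    Q = np.array([[dt**3 / 3.0, dt**2 / 2.0], [dt**2 / 2.0, dt]]) * q
    return StateSpaceModel(
        transition=Phi,
        measurement=[[1.0, 0.0]],
        process_cov=Q,
        measurement_cov=[[measurement_var]],
        initial_mean=list(initial_mean),
        initial_cov=np.eye(2) * initial_var,
    )


def _filter_irregular_level_trend(
    times: np.ndarray,
    values: np.ndarray,
    process_var: float,
    measurement_var: float,
    innovation_clamp: float | None = None,
) -> tuple[StateEstimate, StateSpaceModel]:
    """Trend-model filter with Phi/Q rebuilt per elapsed interval.

    ``innovation_clamp`` (in innovation SDs) caps each measurement residual
    before the update, making the baseline robust to outlying samples so a
    transient artifact does not drag the estimated trend."""
    T = len(values)
    first = values[np.isfinite(values)]
    init_level = first[0] if len(first) else 0.0
    model = local_linear_trend_model(1.0, process_var, measurement_var, (init_level, 0.0))
    s = 2
    prior_means = np.zeros((T, s))
    prior_covs = np.zeros((T, s, s))
    post_means = np.zeros((T, s))
    post_covs = np.zeros((T, s, s))
    gains = np.zeros((T, s, 1))
    mean = model.initial_mean.copy()
    cov = model.initial_cov.copy()
    K = model.measurement
    R = model.measurement_cov
    eye = np.eye(s)
    # store the per-step transition for the smoother
    phis = np.zeros((T, s, s))
    phis[0] = np.eye(s)
    for k in range(T):
        if k > 0:
            dt = times[k] - times[k - 1]
            step = local_linear_trend_model(dt, process_var, measurement_var)
            phis[k] = step.transition
            mean = step.transition @ mean
            cov = _sym(step.transition @ cov @ step.transition.T + step.process_cov)
        prior_means[k] = mean
        prior_covs[k] = cov
        if np.isfinite(values[k]):
            innov_cov = K @ cov @ K.T + R
            A = cov @ K.T @ np.linalg.inv(innov_cov)
            innov = np.array([values[k]]) - K @ mean
            if innovation_clamp is not None:
                lim = innovation_clamp * math.sqrt(float(innov_cov[0, 0]))
                innov = np.clip(innov, -lim, lim)
            mean = mean + A @ innov
            cov = _sym((eye - A @ K) @ cov)
            gains[k] = A
        post_means[k] = mean
        post_covs[k] = cov
    est = StateEstimate(prior_means, prior_covs, post_means, post_covs, gains, times)
    est._phis = phis  # consumed by the irregular smoother below
    return est, model


def _smooth_irregular(est: StateEstimate) -> SmoothedEstimate:
    phis = est._phis
    T = len(est)
    s = est.posterior_means.shape[1]
    means = np.zeros((T, s))
    covs = np.zeros((T, s, s))
    Bs = np.zeros((max(T - 1, 0), s, s))
    means[-1] = est.posterior_means[-1]
    covs[-1] = est.posterior_covs[-1]
    for k in range(T - 2, -1, -1):
        prior_next_inv = np.linalg.inv(est.prior_covs[k + 1])
        B = est.posterior_covs[k] @ phis[k + 1].T @ prior_next_inv
        means[k] = est.posterior_means[k] + B @ (means[k + 1] - est.prior_means[k + 1])
        covs[k] = _sym(est.posterior_covs[k] + B @ (covs[k + 1] - est.prior_covs[k + 1]) @ B.T)
        Bs[k] = B
    return SmoothedEstimate(means, covs, Bs, est.timestamps)


def smooth_frame(
    frame: SensorFrame,
    process_var: float = 1e-4,
    measurement_var: float | None = None,
    band_multiple: float = 2.0,
    innovation_clamp: float | None = 3.0,
) -> SensorFrame:
    """Smooth every channel and append ``_smooth`` / ``_lo`` / ``_hi`` columns.

    Each channel gets an independent local-linear-trend filter + RTS pass;
    ``measurement_var`` defaults to the channel's robust variance estimate.
    Missing samples are bridged by time updates, so the smoothed column has
    no gaps.
    """
    out = frame.copy()
    times = out.times
    for ch in frame.channels:
        vals = frame.values(ch)
        finite = vals[np.isfinite(vals)]
        if len(finite) < 2:
            raise ValidationError(f"channel {ch!r} needs >= 2 observed samples to smooth")
        mvar = measurement_var
        if mvar is None:
            mad = np.median(np.abs(np.diff(finite)))
            mvar = max((mad / 1.349) ** 2, 1e-8)
        est, _ = _filter_irregular_level_trend(times, vals, process_var, mvar,
                                                innovation_clamp=innovation_clamp)
        sm = _smooth_irregular(est)
        lo, hi = error_band(sm, band_multiple, component=0)
        out.data[f"{ch}_smooth"] = sm.means[:, 0]
        out.data[f"{ch}_lo"] = lo
        out.data[f"{ch}_hi"] = hi
    return out
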