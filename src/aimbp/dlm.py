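"""Structured 7-state dynamic linear model of BP/HR homeostasis.

Hidden state (per 15-min step): ``[SBP, DBP, SBP target, DBP target, HR,
HR target, constant]``.  Vitals relax toward their homeostasis targets at
rate ``r_h`` per step; inputs (the spontaneous stroke perturbation and the
per-drug E_max effects) shift the target the vitals relax toward:

    x_t = Phi x_{t-1} + Upsilon u_t + w_t,   w ~ N(0, Q)
    y_t = A x_t + v_t,                        v ~ N(0, R)
    x_0 ~ N(mu0, Sigma0)

Targets and the constant carry no process noise (their rows/columns of Q
and Sigma0 are zero), so they are set entirely by ``mu0``.  With ``r_h = 1``
and zero noise the model reduces exactly to the homeostasis-perturbation
model (see :func:`noise_free_track`).

The Kalman filter, RTS smoother and forward-filtering backward-sampling
(FFBS) here are fully general: they accept any emission layout (e.g. both
cuff and arterial-line BP channels) and per-cell missing data, and tolerate
the model's singular covariances via eigen-based square roots and
pseudo-inverses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .perturbation import PerturbationParams
from .pk import ConcentrationSeries

__all__ = [
    "SBP", "DBP", "SBP_TARGET", "DBP_TARGET", "HR", "HR_TARGET", "CONST",
    "N_STATE",
    "Channel",
    "VitalsSeries",
    "DLMSpec",
    "build_phi",
    "build_upsilon",
    "build_emission",
    "build_inputs",
    "FilterResult",
    "kalman_filter",
    "kalman_smoother",
    "ffbs_sample",
    "noise_free_track",
]

# state-vector layout
SBP, DBP, SBP_TARGET, DBP_TARGET, HR, HR_TARGET, CONST = range(7)
N_STATE = 7

_SIGNAL_STATE = {"SBP": SBP, "DBP": DBP, "HR": HR}
_VITALS = (SBP, DBP, HR)
_STATIC = (SBP_TARGET, DBP_TARGET, HR_TARGET, CONST)


@dataclass(frozen=True)
class Channel:
    """One observation channel: a vital sign measured by one modality."""

    signal: str   # SBP | DBP | HR
    modality: str  # cuff | art | monitor

    def __post_init__(self) -> None:
        if self.signal not in _SIGNAL_STATE:
            raise ValueError(f"unknown signal {self.signal!r}")
        if self.modality not in ("cuff", "art", "monitor"):
            raise ValueError(f"unknown modality {self.modality!r}")


#: simplified 3-channel layout used by the scenario simulations
DEFAULT_CHANNELS = (
    Channel("SBP", "cuff"),
    Channel("DBP", "cuff"),
    Channel("HR", "monitor"),
)

#: 5-channel multi-modal layout (cuff + arterial line + monitor)
MULTIMODAL_CHANNELS = (
    Channel("SBP", "cuff"),
    Channel("DBP", "cuff"),
    Channel("SBP", "art"),
    Channel("DBP", "art"),
    Channel("HR", "monitor"),
)


@dataclass
class VitalsSeries:
    """Observed vitals over a uniform grid with per-cell missingness.

    ``y`` is (T, m); ``mask`` is True where a measurement exists.  Missing
    cells of ``y`` hold NaN.
    """

    time: np.ndarray
    y: np.ndarray
    channels: tuple[Channel, ...]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2 or self.y.shape[0] != self.time.shape[0]:
            raise ValueError("y must be (T, m) matching the time grid")
        if len(self.channels) != self.y.shape[1]:
            raise ValueError("one channel descriptor per column required")
        if self.mask is None:
            self.mask = ~np.isnan(self.y)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.y.shape:
                raise ValueError("mask must match y's shape")

    @property
    def n_steps(self) -> int:
        return self.y.shape[0]

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else 0.0

    def channel_index(self, signal: str, modality: str | None = None) -> int:
        for j, ch in enumerate(self.channels):
            if ch.signal == signal and (modality is None or ch.modality == modality):
                return j
        raise KeyError((signal, modality))

    def column(self, signal: str, modality: str | None = None) -> np.ndarray:
        return self.y[:, self.channel_index(signal, modality)]


def build_phi(r_h: float) -> np.ndarray:
    """Transition matrix: vitals relax toward their targets at rate ``r_h``.

    Each vital-sign row carries ``1 - r_h`` on itself and ``r_h`` on its
    homeostasis target (rows sum to 1); target and constant rows are
    identity, making them invariant over time.
    """
    if not 0.0 <= r_h <= 1.0:
        raise ValueError(f"r_h must lie in [0, 1], got {r_h}")
    phi = np.eye(N_STATE)
    for vital, target in ((SBP, SBP_TARGET), (DBP, DBP_TARGET), (HR, HR_TARGET)):
        phi[vital, vital] = 1.0 - r_h
        phi[vital, target] = r_h
    return phi


def build_upsilon(r_h: float, ratio_sd: float, n_drugs: int) -> np.ndarray:
    """Input-response matrix, shape (7, 1 + n_drugs).

    Column 1 is the spontaneous stroke perturbation; the rest are drug
    effects.  All inputs act on systolic BP with weight ``r_h`` and on
    diastolic BP with weight ``r_h * ratio_sd`` (inputs shift the target the
    vitals relax toward); no input touches HR, the targets, or the constant.
    """
    if not 0.0 <= r_h <= 1.0:
        raise ValueError(f"r_h must lie in [0, 1], got {r_h}")
    if n_drugs < 0:
        raise ValueError("n_drugs must be >= 0")
    ups = np.zeros((N_STATE, 1 + n_drugs))
    ups[SBP, :] = r_h
    ups[DBP, :] = r_h * ratio_sd
    return ups


def build_emission(channels: Sequence[Channel] = DEFAULT_CHANNELS) -> np.ndarray:
    """Emission matrix A: each channel reads its signal's hidden state directly."""
    a = np.zeros((len(channels), N_STATE))
    for j, ch in enumerate(channels):
        a[j, _SIGNAL_STATE[ch.signal]] = 1.0
    return a


def build_inputs(
    params: PerturbationParams,
    conc: Mapping[str, ConcentrationSeries],
    n_steps: int,
) -> np.ndarray:
    """Input series u, shape (T, 1 + n_drugs): spontaneous column then drugs.

    ``u_t`` is evaluated from step-``t`` quantities: ``u_t[0] = B_max
    (1-r_B)^t`` and ``u_t[1+j] = E_max_j c_j(t) / (EC50_j + c_j(t))``.
    """
    from .perturbation import p_med, p_spon

    t = np.arange(n_steps)
    u = np.zeros((n_steps, 1 + len(params.drugs)))
    u[:, 0] = p_spon(t, params.b_max, params.r_b)
    for j, d in enumerate(params.drugs):
        u[:, 1 + j] = p_med(conc[d.name].values, d.e_max, d.ec50)
    return u


def _check_psd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(mat)
    if eig.min() < -1e-8 * max(1.0, eig.max()):
        raise ValueError(f"{name} must be positive semidefinite")
    return 0.5 * (mat + mat.T)


@dataclass
class DLMSpec:
    """Fully specified DLM: matrices, noise covariances and initial law."""

    phi: np.ndarray
    upsilon: np.ndarray
    a: np.ndarray
    q: np.ndarray
    r: np.ndarray
    mu0: np.ndarray
    sigma0: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.upsilon = np.asarray(self.upsilon, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.mu0 = np.asarray(self.mu0, dtype=float)
        n = self.phi.shape[0]
        if self.phi.shape != (n, n):
            raise ValueError("phi must be square")
        if self.upsilon.shape[0] != n or self.a.shape[1] != n or self.mu0.shape != (n,):
            raise ValueError("inconsistent state dimension")
        self.q = _check_psd(self.q, "Q")
        self.r = _check_psd(self.r, "R")
        self.sigma0 = _check_psd(self.sigma0, "Sigma0")
        if self.q.shape != (n, n) or self.sigma0.shape != (n, n):
            raise ValueError("Q and Sigma0 must be n x n")
        m = self.a.shape[0]
        if self.r.shape != (m, m):
            raise ValueError("R must be m x m")

    @property
    def n_state(self) -> int:
        return self.phi.shape[0]

    @property
    def n_obs(self) -> int:
        return self.a.shape[0]


def make_spec(
    r_h: float,
    ratio_sd: float,
    n_drugs: int,
    mu0: np.ndarray,
    q_diag: Sequence[float],
    r_diag: Sequence[float],
    sigma0_vitals: float | Sequence[float] = 100.0,
    channels: Sequence[Channel] = DEFAULT_CHANNELS,
) -> DLMSpec:
    """Assemble the structured 7-state spec from scalar configuration.

    ``q_diag`` gives process variances for (SBP, DBP, HR); ``r_diag`` gives
    one measurement variance per channel.  ``sigma0_vitals`` is the initial
    variance of the vitals block; target/constant rows of Q and Sigma0 are
    forced to zero so homeostasis targets depend on ``mu0`` alone.
    """
    q = np.zeros((N_STATE, N_STATE))
    q[SBP, SBP], q[DBP, DBP], q[HR, HR] = q_diag
    r = np.diag(np.asarray(r_diag, dtype=float))
    sigma0 = np.zeros((N_STATE, N_STATE))
    s0 = np.broadcast_to(np.asarray(sigma0_vitals, dtype=float), (3,))
    sigma0[SBP, SBP], sigma0[DBP, DBP], sigma0[HR, HR] = s0
    return DLMSpec(
        phi=build_phi(r_h),
        upsilon=build_upsilon(r_h, ratio_sd, n_drugs),
        a=build_emission(channels),
        q=q,
        r=r,
        mu0=np.asarray(mu0, dtype=float),
        sigma0=sigma0,
    )


@dataclass
class FilterResult:
    pred_mean: np.ndarray   # (T, n) mean of x_t | y_{0:t-1}
    pred_cov: np.ndarray    # (T, n, n)
    filt_mean: np.ndarray   # (T, n) mean of x_t | y_{0:t}
    filt_cov: np.ndarray    # (T, n, n)
    loglik: float


def _symmetrize(p: np.ndarray) -> np.ndarray:
    return 0.5 * (p + p.T)


def kalman_filter(
    spec: DLMSpec,
    y: np.ndarray,
    u: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> FilterResult:
    """Exact Gaussian forward filter with per-cell missing data.

    At step 0 the prior ``N(mu0, Sigma0)`` is updated with ``y_0``; inputs
    act from step 1 on (``x_t = Phi x_{t-1} + Upsilon u_t + w_t``).  At a
    step with some channels missing, only the observed rows of A and R are
    used; a fully missing step is a pure prediction.  Uses the Joseph-form
    covariance update and symmetrization each step for numerical stability.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    t_len, m = y.shape
    n = spec.n_state
    if m != spec.n_obs:
        raise ValueError("y has wrong number of channels")
    if u is None:
        u = np.zeros((t_len, spec.upsilon.shape[1]))
    u = np.asarray(u, dtype=float)
    if mask is None:
        mask = ~np.isnan(y)

    pred_mean = np.empty((t_len, n))
    pred_cov = np.empty((t_len, n, n))
    filt_mean = np.empty((t_len, n))
    filt_cov = np.empty((t_len, n, n))
    loglik = 0.0

    mean, cov = spec.mu0.copy(), spec.sigma0.copy()
    eye = np.eye(n)
    for t in range(t_len):
        if t > 0:
            mean = spec.phi @ mean + spec.upsilon @ u[t]
            cov = _symmetrize(spec.phi @ cov @ spec.phi.T + spec.q)
        pred_mean[t], pred_cov[t] = mean, cov

        obs = mask[t]
        if obs.any():
            a_t = spec.a[obs]
            r_t = spec.r[np.ix_(obs, obs)]
            innov = y[t, obs] - a_t @ mean
            s = _symmetrize(a_t @ cov @ a_t.T + r_t)
            # eigen route tolerates degenerate (zero-variance) channels:
            # the density lives on the non-null subspace of S
            vals, vecs = np.linalg.eigh(s)
            keep = vals > max(1e-12, 1e-12 * vals.max())
            z = vecs[:, keep].T @ innov
            loglik += -0.5 * (
                z @ (z / vals[keep])
                + keep.sum() * np.log(2.0 * np.pi)
                + np.log(vals[keep]).sum()
            )
            s_pinv = (vecs[:, keep] / vals[keep]) @ vecs[:, keep].T
            gain = cov @ a_t.T @ s_pinv
            mean = mean + gain @ innov
            joseph = eye - gain @ a_t
            cov = _symmetrize(joseph @ cov @ joseph.T + gain @ r_t @ gain.T)
        filt_mean[t], filt_cov[t] = mean, cov

    return FilterResult(pred_mean, pred_cov, filt_mean, filt_cov, float(loglik))


def kalman_smoother(
    spec: DLMSpec, filt: FilterResult
) -> tuple[np.ndarray, np.ndarray]:
    """RTS smoother: means and covariances of ``x_t | y_{0:T}``."""
    t_len, n = filt.filt_mean.shape
    sm_mean = filt.filt_mean.copy()
    sm_cov = filt.filt_cov.copy()
    for t in range(t_len - 2, -1, -1):
        p_pred = filt.pred_cov[t + 1]
        j = filt.filt_cov[t] @ spec.phi.T @ np.linalg.pinv(p_pred)
        sm_mean[t] = filt.filt_mean[t] + j @ (sm_mean[t + 1] - filt.pred_mean[t + 1])
        sm_cov[t] = _symmetrize(
            filt.filt_cov[t] + j @ (sm_cov[t + 1] - p_pred) @ j.T
        )
    return sm_mean, sm_cov


def _sample_gaussian(
    rng: np.random.Generator, mean: np.ndarray, cov: np.ndarray
) -> np.ndarray:
    """Draw from a possibly degenerate Gaussian via an eigen square root."""
    vals, vecs = np.linalg.eigh(_symmetrize(cov))
    vals = np.clip(vals, 0.0, None)
    root = vecs * np.sqrt(vals)
    return mean + root @ rng.standard_normal(mean.shape[0])


def ffbs_sample(
    spec: DLMSpec,
    y: np.ndarray,
    u: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    filt: FilterResult | None = None,
) -> np.ndarray:
    """One exact draw of the hidden-state path ``x_0..x_{T-1} | y`` (FFBS).

    Degenerate components (targets, constant: zero prior and process
    variance) are handled naturally: their conditional variance is zero so
    the draw pins them to their deterministic values.  Deterministic under a
    fixed ``rng`` seed.
    """
    rng = np.random.default_rng(rng)
    if u is None:
        u = np.zeros((np.atleast_2d(y).shape[0], spec.upsilon.shape[1]))
    if filt is None:
        filt = kalman_filter(spec, y, u, mask)
    t_len, n = filt.filt_mean.shape

    x = np.empty((t_len, n))
    x[-1] = _sample_gaussian(rng, filt.filt_mean[-1], filt.filt_cov[-1])
    for t in range(t_len - 2, -1, -1):
        p_pred = filt.pred_cov[t + 1]
        j = filt.filt_cov[t] @ spec.phi.T @ np.linalg.pinv(p_pred, hermitian=True)
        mean = filt.filt_mean[t] + j @ (x[t + 1] - filt.pred_mean[t + 1])
        cov = filt.filt_cov[t] - j @ p_pred @ j.T
        x[t] = _sample_gaussian(rng, mean, cov)
    return x


def noise_free_track(
    params: PerturbationParams,
    conc: Mapping[str, ConcentrationSeries],
    n_steps: int,
    hr_h: float = 80.0,
) -> np.ndarray:
    """Deterministic DLM run with ``r_h = 1`` and zero noise, returning x (T, 7).

    With the homeostasis rate at 1 and Q = R = 0, the emitted SBP equals
    ``SBP_H + P_spon(t) + sum P_med(t)`` exactly (and DBP its scaled
    counterpart) -- the DLM collapses to the perturbation model.
    """
    u = build_inputs(params, conc, n_steps)
    phi = build_phi(1.0)
    ups = build_upsilon(1.0, params.ratio_sd, len(params.drugs))
    x = np.empty((n_steps, N_STATE))
    x0 = np.array([
        params.sbp_h + u[0].sum(),
        params.dbp_h + params.ratio_sd * u[0].sum(),
        params.sbp_h,
        params.dbp_h,
        hr_h,
        hr_h,
        1.0,
    ])
    x[0] = x0
    for t in range(1, n_steps):
        x[t] = phi @ x[t - 1] + ups @ u[t]
    return x
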