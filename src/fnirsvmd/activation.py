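"""Activation mapping: expected hemodynamic response, robust GLM, t-maps, ROI.

Per channel `i` and stimulus epoch `j` the measured HbO trace is modelled as

    y_ij = β_ij · X_r + α_ij · 1 + ε_ij

where ``X_r`` is the expected hemodynamic response (a canonical double-gamma
impulse response convolved with the stimulus boxcar, peak-normalized to 1),
``β`` the activation strength, ``α`` a baseline offset.  β is estimated by
iteratively reweighted least squares (IRLS) with Tukey's bisquare weight
function, and the per-channel statistic is ``t = β̂ / SE(β̂)``.  A channel is
declared active — part of the region of interest (ROI) — when its t-value
strictly exceeds the critical value of the Student t distribution
(one-tailed; 1.67 at 63 degrees of freedom, α = 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .paradigm import StimulusSchedule, samples_per_epoch, onset_to_index

__all__ = [
    "ExpectedResponse",
    "RobustFitResult",
    "ChannelActivation",
    "ActivationMap",
    "hrf_double_gamma",
    "build_expected_response",
    "session_regressor",
    "RobustGLM",
    "robust_fit",
    "t_critical",
    "fit_condition",
    "select_roi",
]

#: Default bisquare tuning constant (95% Gaussian efficiency).
BISQUARE_C = 4.685
#: MAD-to-sigma consistency factor for Gaussian residuals.
MAD_SCALE = 0.6745


# ---------------------------------------------------------------------------
# Expected hemodynamic response
# ---------------------------------------------------------------------------

def hrf_double_gamma(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response at times ``t`` (s).

    Difference of two gamma densities (unit scale): a positive lobe with
    shape ``peak_delay`` and an undershoot with shape ``undershoot_delay``
    scaled by ``undershoot_ratio``.  Zero for t < 0.
    """
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, a=peak_delay) - undershoot_ratio * stats.gamma.pdf(
        t, a=undershoot_delay
    )
    return np.where(t < 0, 0.0, h)


@dataclass(frozen=True)
class ExpectedResponse:
    """Peak-normalized expected response regressor for one epoch window."""

    xr: np.ndarray
    sampling_hz: float
    stimulus_s: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "xr", np.asarray(self.xr, dtype=float))

    def __len__(self) -> int:
        return len(self.xr)

    def restrict(self, window_s: float) -> "ExpectedResponse":
        """Truncate the regressor to the first ``window_s`` seconds."""
        n = samples_per_epoch(window_s, self.sampling_hz)
        if n > len(self.xr):
            raise ValueError("restriction window exceeds the regressor length")
        return ExpectedResponse(
            self.xr[:n], self.sampling_hz, self.stimulus_s, (self.window[0], self.window[0] + window_s)
        )


def build_expected_response(
    stimulus_s: float,
    sampling_hz: float,
    window: tuple[float, float] = (0.0, 35.0),
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> ExpectedResponse:
    """Expected response for a single stimulus: HRF ⊛ boxcar, peak = 1.

    The window is relative to stimulus onset; the default (0, 35) covers the
    15 s stimulus and 20 s of the rest period — N = 64 samples at 1.81 Hz.
    A zero-duration stimulus yields an all-zero regressor.
    """
    if window[1] <= window[0]:
        raise ValueError("window must have positive length")
    n = samples_per_epoch(window[1] - window[0], sampling_hz)
    if n < 1:
        raise ValueError("window shorter than one sample")
    dt = 1.0 / sampling_hz
    t = window[0] + np.arange(n) * dt
    n_box = samples_per_epoch(stimulus_s, sampling_hz) if stimulus_s > 0 else 0
    if n_box == 0:
        return ExpectedResponse(np.zeros(n), sampling_hz, stimulus_s, window)
    # Convolve on a grid starting at onset 0; window start may precede onset.
    t_full = np.arange(0.0, window[1] + dt, dt)
    h = hrf_double_gamma(t_full, peak_delay, undershoot_delay, undershoot_ratio)
    box = np.zeros(len(t_full))
    box[:n_box] = 1.0
    conv = np.convolve(box, h)[: len(t_full)] * dt
    xr = np.interp(t, t_full, conv, left=0.0)
    peak = xr.max()
    if peak > 0:
        xr = xr / peak
    return ExpectedResponse(xr, sampling_hz, stimulus_s, window)


def session_regressor(
    schedule: StimulusSchedule,
    valence: str | None = None,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Full-session expected-response vector for the events of one schedule.

    Each event contributes an HRF-convolved boxcar; the whole vector is
    scaled so that an isolated event peaks at 1, making β interpretable as
    the per-event response amplitude in µM.  Restrict to one valence with
    ``valence=...``; with ``None`` all events contribute.
    """
    design = schedule.design
    fs = design.sampling_hz
    n = design.n_samples
    dt = 1.0 / fs
    t = np.arange(n) * dt
    h = hrf_double_gamma(t, peak_delay, undershoot_delay, undershoot_ratio)
    box = np.zeros(n)
    for ev in schedule.events:
        if valence is not None and ev.valence != valence:
            continue
        i0 = onset_to_index(ev.onset_s, fs)
        i1 = min(i0 + samples_per_epoch(ev.duration_s, fs), n) if ev.duration_s > 0 else i0
        box[i0:i1] = 1.0
    conv = np.convolve(box, h)[:n] * dt
    # scale so an isolated event peaks at 1
    single = build_expected_response(
        design.stimulus_s, fs, (0.0, design.stimulus_s + design.rest_s),
        peak_delay, undershoot_delay, undershoot_ratio,
    )
    n_box = samples_per_epoch(design.stimulus_s, fs)
    raw_box = np.zeros(len(single.xr))
    raw_box[:n_box] = 1.0
    t_single = np.arange(len(single.xr)) * dt
    raw_peak = (np.convolve(raw_box, hrf_double_gamma(t_single, peak_delay, undershoot_delay, undershoot_ratio))[: len(single.xr)] * dt).max()
    if raw_peak > 0:
        conv = conv / raw_peak
    return conv


# ---------------------------------------------------------------------------
# Robust GLM (IRLS with bisquare weights)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RobustFitResult:
    """Result of one robust single-regressor fit (β̂, SE, t = β̂/SE)."""

    beta_hat: float
    alpha_hat: float
    se: float
    t: float
    dof: int
    p: float
    converged: bool
    iterations: int
    resid: np.ndarray = field(repr=False)


class RobustGLM(BaseEstimator, RegressorMixin):
    """Robust single-regressor linear model fit by IRLS with bisquare weights.

    Fits ``y = β·x + α`` minimizing the Tukey bisquare ρ of residuals
    standardized by the MAD scale estimate (``median|r| / 0.6745``).  With
    ``irls=False`` weights are forced to 1 and the fit is ordinary least
    squares.  The standard error of β̂ uses the final-iteration robust
    covariance with the standard small-sample correction; the t-statistic
    ``t_ = coef_ / se_`` is referred to a Student t with ``dof_`` degrees of
    freedom (default convention N−1, configurable to N−2).

    Parameters
    ----------
    c : bisquare tuning constant (default 4.685, 95% Gaussian efficiency).
    tol : convergence threshold on the max absolute coefficient change.
    max_iter : IRLS iteration cap; non-convergence is flagged, not fatal.
    dof : ``"n_minus_1"`` (reference convention) or ``"n_minus_2"``.
    irls : when False, a plain OLS fit (unit weights) is performed.
    """

    def __init__(
        self,
        c: float = BISQUARE_C,
        tol: float = 1e-8,
        max_iter: int = 50,
        dof: Literal["n_minus_1", "n_minus_2"] = "n_minus_1",
        irls: bool = True,
    ):
        self.c = c
        self.tol = tol
        self.max_iter = max_iter
        self.dof = dof
        self.irls = irls

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _psi_weight(u: np.ndarray, c: float) -> np.ndarray:
        """Bisquare weight w(u) = (1 − (u/c)²)² for |u| < c, else 0."""
        z = np.clip(1.0 - (u / c) ** 2, 0.0, None)
        return z * z

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("RobustGLM is a single-regressor model")
            X = X[:, 0]
        if X.shape != y.shape:
            raise ValueError("x and y must have equal length")
        n = len(y)
        if n < 3:
            raise ValueError("need at least 3 samples")
        if np.ptp(X) == 0:
            raise ValueError("regressor is constant; beta is inestimable")

        D = np.column_stack([X, np.ones(n)])  # design: [xr, intercept]
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        converged = not self.irls
        it = 0
        w = np.ones(n)
        scale = 0.0
        if self.irls:
            for it in range(1, self.max_iter + 1):
                r = y - D @ beta
                scale = np.median(np.abs(r)) / MAD_SCALE
                if scale <= np.finfo(float).tiny * 1e6:
                    # (near-)exact fit: residuals are numerically zero
                    w = np.ones(n)
                    converged = True
                    break
                w = self._psi_weight(r / scale, self.c)
                if w.sum() <= 2 or np.ptp(X[w > 0]) == 0:
                    # degenerate weighting; keep last estimate
                    break
                Dw = D * w[:, None]
                beta_new = np.linalg.solve(D.T @ Dw, Dw.T @ y)
                delta = np.max(np.abs(beta_new - beta))
                beta = beta_new
                if delta < self.tol:
                    converged = True
                    break

        resid = y - D @ beta
        p_par = 2
        n_dof = n - 1 if self.dof == "n_minus_1" else n - p_par
        if self.irls and scale > np.finfo(float).tiny * 1e6:
            se = self._robust_se(D, resid, scale, n, p_par)
        else:
            # OLS covariance (also used for numerically exact robust fits)
            sigma2 = resid @ resid / max(n - p_par, 1)
            cov = sigma2 * np.linalg.inv(D.T @ D)
            se = np.sqrt(np.diag(cov))

        self.coef_ = float(beta[0])
        self.intercept_ = float(beta[1])
        self.se_ = float(se[0])
        self.t_ = self.coef_ / self.se_ if self.se_ > 0 else np.inf * np.sign(self.coef_)
        self.dof_ = int(n_dof)
        self.p_ = float(stats.t.sf(self.t_, n_dof))
        self.converged_ = bool(converged)
        self.n_iter_ = int(it)
        self.resid_ = resid
        self.n_features_in_ = 1
        if not converged and self.irls:
            warnings.warn("IRLS did not converge; returning last iterate", RuntimeWarning)
        return self

    def _robust_se(self, D, resid, scale, n, p_par) -> np.ndarray:
        """Robust covariance of the estimate (H1-type, bisquare).

        ``k² · [Σψ(r/s)²·s² / (n−p)] / mean(ψ′)² · (XᵀX)⁻¹`` with the
        standard correction ``k = 1 + p·var(ψ′)/(n·mean(ψ′)²)``.
        """
        u = resid / scale
        c = self.c
        inside = np.abs(u) < c
        psi = np.where(inside, u * (1 - (u / c) ** 2) ** 2, 0.0)
        dpsi = np.where(inside, (1 - (u / c) ** 2) * (1 - 5 * (u / c) ** 2), 0.0)
        m1 = dpsi.mean()
        if m1 <= 0:
            # pathological weighting; fall back to OLS-style variance
            sigma2 = resid @ resid / max(n - p_par, 1)
            return np.sqrt(np.diag(sigma2 * np.linalg.inv(D.T @ D)))
        k = 1.0 + p_par * dpsi.var() / (n * m1 * m1)
        num = (psi @ psi) * scale * scale / (n - p_par)
        cov = k * k * num / (m1 * m1) * np.linalg.inv(D.T @ D)
        return np.sqrt(np.diag(cov))

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.coef_ * X + self.intercept_

    def result_(self) -> RobustFitResult:
        """Bundle the fitted attributes as a :class:`RobustFitResult`."""
        return RobustFitResult(
            beta_hat=self.coef_,
            alpha_hat=self.intercept_,
            se=self.se_,
            t=self.t_,
            dof=self.dof_,
            p=self.p_,
            converged=self.converged_,
            iterations=self.n_iter_,
            resid=self.resid_,
        )


def robust_fit(xr: ExpectedResponse | np.ndarray, y: np.ndarray, **params) -> RobustFitResult:
    """Robust fit of one epoch against the expected response (thin wrapper)."""
    x = xr.xr if isinstance(xr, ExpectedResponse) else np.asarray(xr, dtype=float)
    return RobustGLM(**params).fit(x, np.asarray(y, dtype=float)).result_()


def t_critical(dof: int, alpha: float = 0.05) -> float:
    """Upper-tail Student-t critical value (1.6694 → "1.67" at dof 63)."""
    if dof < 1:
        raise ValueError("dof must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.t.ppf(1.0 - alpha, dof))


# ---------------------------------------------------------------------------
# Condition-level maps and ROI selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelActivation:
    """Per-channel activation summary for one condition."""

    channel: int | str
    beta: float
    se: float
    t: float
    p: float
    n_trials: int


@dataclass(frozen=True)
class ActivationMap:
    """Per-channel activation for one (category, valence) condition."""

    entries: tuple[ChannelActivation, ...]
    mode: Literal["per-trial", "averaged"]
    valence: str
    t_crt: float
    dof: int

    @property
    def t_values(self) -> np.ndarray:
        return np.array([e.t for e in self.entries])

    @property
    def channels(self) -> list:
        return [e.channel for e in self.entries]

    @property
    def active(self) -> list:
        return [e.channel for e in self.entries if e.t > self.t_crt]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "channel": e.channel,
                    "beta": e.beta,
                    "se": e.se,
                    "t": e.t,
                    "p": e.p,
                    "active": e.t > self.t_crt,
                }
                for e in self.entries
            ]
        )


def fit_condition(
    epochs,
    valence: str,
    xr: ExpectedResponse,
    mode: Literal["per-trial", "averaged"] = "per-trial",
    alpha: float = 0.05,
    **glm_params,
) -> ActivationMap:
    """Fit the robust GLM per channel for one valence and assemble a t-map.

    ``per-trial`` fits every epoch separately and averages β, SE and t
    across trials (trial-averaged t-map style); ``averaged`` first averages
    the epochs of the valence, then fits once per channel.  For a single
    epoch the two modes coincide.
    """
    sub = epochs.select(valence)
    if sub.n_trials == 0:
        raise ValueError(f"no epochs with valence {valence!r}")
    n_ch = sub.n_channels
    xvec = xr.xr
    if len(xvec) != sub.n_times:
        raise ValueError("expected response length does not match epoch length")

    def _one(y: np.ndarray) -> RobustFitResult:
        return robust_fit(xvec, y, **glm_params)

    entries = []
    dof = None
    for ci in range(n_ch):
        if mode == "averaged":
            res = _one(sub.epochs[:, ci, :].mean(axis=0))
            beta, se, t, p, dof = res.beta_hat, res.se, res.t, res.p, res.dof
        elif mode == "per-trial":
            fits = [_one(sub.epochs[ti, ci, :]) for ti in range(sub.n_trials)]
            beta = float(np.mean([f.beta_hat for f in fits]))
            se = float(np.mean([f.se for f in fits]))
            t = float(np.mean([f.t for f in fits]))
            dof = fits[0].dof
            p = float(stats.t.sf(t, dof))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        entries.append(
            ChannelActivation(
                channel=sub.channel_labels[ci], beta=beta, se=se, t=t, p=p,
                n_trials=sub.n_trials,
            )
        )
    return ActivationMap(
        entries=tuple(entries),
        mode=mode,
        valence=valence,
        t_crt=t_critical(dof, alpha),
        dof=dof,
    )


def select_roi(amap: ActivationMap, t_crt: float | None = None) -> list:
    """Channels whose t-value strictly exceeds the critical value.

    An empty result is allowed and signalled with a warning (the caller
    decides on a fallback).
    """
    if len(amap.entries) == 0:
        raise ValueError("activation map is empty")
    thr = amap.t_crt if t_crt is None else t_crt
    roi = [e.channel for e in amap.entries if e.t > thr]
    if not roi:
        warnings.warn(
            f"no channel exceeds t_crt = {thr:.4g} for valence {amap.valence!r}",
            UserWarning,
        )
    return roi
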