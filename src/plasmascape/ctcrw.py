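"""Continuous-time correlated random walk (integrated OU) interpolation.

The velocity of the animal follows an Ornstein-Uhlenbeck process
``dv = -beta v dt + sigma dW`` and position integrates velocity. Over a gap
``dt`` the transition of the per-axis state ``[x, v]`` is Gaussian with
closed-form mean and covariance, so the model is an exact linear-Gaussian
state space: parameters ``(beta, sigma)`` are estimated by maximising the
Kalman-filter innovation likelihood, and positions at arbitrary output
times are read from a fixed-interval (RTS) smoother run over the union of
observation and output times. Computation is done in a local equirectangular
km frame centred on the first fix; observation error is a fixed small
standard deviation appropriate to GPS.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .geo import KM_PER_DEGREE


class CtcrwConvergenceError(RuntimeError):
    """Maximum-likelihood fit failed to converge."""


def _transition(beta: float, sigma: float, dt: np.ndarray):
    """Per-axis transition matrices F (2x2) and noise covariances Q for gaps dt."""
    e = np.exp(-beta * dt)
    e2 = np.exp(-2.0 * beta * dt)
    F = np.zeros(dt.shape + (2, 2))
    F[..., 0, 0] = 1.0
    F[..., 0, 1] = (1.0 - e) / beta
    F[..., 1, 1] = e
    s2 = sigma ** 2
    Q = np.zeros_like(F)
    Q[..., 0, 0] = s2 / beta ** 2 * (dt - 2.0 * (1.0 - e) / beta + (1.0 - e2) / (2.0 * beta))
    Q[..., 0, 1] = Q[..., 1, 0] = s2 / (2.0 * beta ** 2) * (1.0 - e) ** 2
    Q[..., 1, 1] = s2 * (1.0 - e2) / (2.0 * beta)
    return F, Q


def _kalman(times, obs, obs_idx, beta, sigma, obs_var, return_states=False):
    """Filter (and optionally smooth) one axis over the merged time line.

    ``obs_idx[k]`` gives the row of ``times`` at which ``obs[k]`` was made;
    other times are pure predictions. Returns the log-likelihood, and with
    ``return_states`` also the RTS-smoothed state means.
    """
    n = len(times)
    F_all, Q_all = _transition(beta, sigma, np.diff(times))
    H = np.array([1.0, 0.0])
    # initial state: first observation, zero velocity, small position variance,
    # stationary velocity variance
    x = np.array([obs[0], 0.0])
    P = np.diag([obs_var, sigma ** 2 / (2.0 * beta)])
    is_obs = np.full(n, -1, dtype=int)
    is_obs[obs_idx] = np.arange(len(obs_idx))
    ll = 0.0
    xs_pred = np.zeros((n, 2)); Ps_pred = np.zeros((n, 2, 2))
    xs_filt = np.zeros((n, 2)); Ps_filt = np.zeros((n, 2, 2))
    for t in range(n):
        if t > 0:
            F, Q = F_all[t - 1], Q_all[t - 1]
            x = F @ x
            P = F @ P @ F.T + Q
        xs_pred[t], Ps_pred[t] = x, P
        k = is_obs[t]
        if k >= 0 and not (t == 0):
            y = obs[k] - H @ x
            # guard against loss of positivity at extreme trial parameters
            S = max(H @ P @ H + obs_var, 1e-12 * obs_var)
            K = (P @ H) / S
            x = x + K * y
            P = P - np.outer(K, H @ P)
            ll += -0.5 * (np.log(2.0 * np.pi * S) + y * y / S)
        elif k >= 0 and t == 0:
            pass  # first obs consumed by the initial state
        xs_filt[t], Ps_filt[t] = x, P
    if not return_states:
        return ll
    # RTS smoother
    xs = xs_filt.copy()
    Ps = Ps_filt.copy()
    for t in range(n - 2, -1, -1):
        F = F_all[t]
        # tiny jitter keeps the inverse finite when Q is numerically zero
        C = Ps_filt[t] @ F.T @ np.linalg.inv(Ps_pred[t + 1] + 1e-12 * np.eye(2))
        xs[t] = xs_filt[t] + C @ (xs[t + 1] - xs_pred[t + 1])
        Ps[t] = Ps_filt[t] + C @ (Ps[t + 1] - Ps_pred[t + 1]) @ C.T
    return ll, xs


def smooth_track(times_s, lon, lat, out_times_s, obs_sd_km: float = 0.05,
                 beta_bounds=(1e-3, 50.0), sigma_bounds=(1e-4, 500.0),
                 maxiter: int = 200, max_fit_points: int = 200):
    """Fit the CTCRW to one trip and return positions at ``out_times_s``.

    Times in seconds; internally the model runs in hours and km. The
    likelihood is maximised on at most ``max_fit_points`` evenly thinned
    fixes (the smoother then runs on the full track), which keeps long
    2-minute penguin trips tractable without changing the estimate
    materially. Raises :class:`CtcrwConvergenceError` if the optimiser
    fails.
    """
    times_h = (np.asarray(times_s, float) - times_s[0]) / 3600.0
    lat0 = float(np.mean(lat))
    x_km = (np.asarray(lon, float) - lon[0]) * KM_PER_DEGREE * np.cos(np.radians(lat0))
    y_km = (np.asarray(lat, float) - lat[0]) * KM_PER_DEGREE
    obs_var = obs_sd_km ** 2

    if len(times_h) > max_fit_points:
        thin = np.unique(np.linspace(0, len(times_h) - 1, max_fit_points).astype(int))
    else:
        thin = np.arange(len(times_h))

    def nll(logp):
        beta, sigma = np.exp(logp)
        total = 0.0
        with np.errstate(all="ignore"):  # extreme trial params may overflow
            for obs in (x_km, y_km):
                total += _kalman(times_h[thin], obs[thin], np.arange(len(thin)),
                                 beta, sigma, obs_var)
        return -total if np.isfinite(total) else 1e300

    # coarse grid start then local refinement keeps the fit off bad ridges
    grid = [(b, s) for b in (0.05, 0.5, 5.0) for s in (0.5, 5.0, 50.0)]
    best0 = min(grid, key=lambda p: nll(np.log(p)))
    res = minimize(nll, np.log(best0), method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6})
    if not np.isfinite(res.fun):
        raise CtcrwConvergenceError("CTCRW likelihood non-finite")
    beta, sigma = np.clip(np.exp(res.x), [beta_bounds[0], sigma_bounds[0]],
                          [beta_bounds[1], sigma_bounds[1]])

    out_h = (np.asarray(out_times_s, float) - times_s[0]) / 3600.0
    merged = np.union1d(np.round(times_h, 9), np.round(out_h, 9))
    obs_idx = np.searchsorted(merged, np.round(times_h, 9))
    out_idx = np.searchsorted(merged, np.round(out_h, 9))
    sx = _kalman(merged, x_km, obs_idx, beta, sigma, obs_var, return_states=True)[1]
    sy = _kalman(merged, y_km, obs_idx, beta, sigma, obs_var, return_states=True)[1]
    out_lon = lon[0] + sx[out_idx, 0] / (KM_PER_DEGREE * np.cos(np.radians(lat0)))
    out_lat = lat[0] + sy[out_idx, 0] / KM_PER_DEGREE
    return out_lon, out_lat
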