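"""Foraging-state labelling from step speed and turning angle.

Flying birds: a four-state expectation-maximisation binary clustering of
(speed, |turning angle|) — a Gaussian mixture initialised at the four
quadrants of the per-variable medians and bound to those quadrants after
fitting. The low-speed/high-turn state ("actively sitting") is foraging.

Diving birds (penguins): steps slower than the species-pooled mean speed
are foraging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .errors import InvalidTripError
from .geo import haversine_km, initial_bearing_rad
from .tracks import Trip

log = logging.getLogger(__name__)

#: label order: (speed-class, turn-class); foraging is low speed / high turn
LABELS = ("LL", "LH", "HL", "HH")
FORAGING_LABEL = "LH"


def step_metrics(trip: Trip) -> pd.DataFrame:
    """Per-fix speed (to the next fix, km/h) and signed heading change (rad).

    Speeds are defined for fixes 0..n-2; turning angles only for interior
    fixes (need both an incoming and an outgoing segment); undefined entries
    are NaN.
    """
    if len(trip) < 3:
        raise InvalidTripError("need at least 3 fixes for step metrics")
    t = trip.times_s
    if np.any(np.diff(t) <= 0):
        raise InvalidTripError("duplicate or unordered timestamps")
    lon = trip.df["lon"].to_numpy(float)
    lat = trip.df["lat"].to_numpy(float)
    dist = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    speed = np.full(len(trip), np.nan)
    speed[:-1] = np.atleast_1d(dist) / (np.diff(t) / 3600.0)
    heading = initial_bearing_rad(lon[:-1], lat[:-1], lon[1:], lat[1:])
    heading = np.atleast_1d(heading)
    turn = np.full(len(trip), np.nan)
    dh = np.diff(heading)
    turn[1:-1] = (dh + np.pi) % (2.0 * np.pi) - np.pi
    return pd.DataFrame({"speed_kmh": speed, "turn_rad": turn})


@dataclass
class _ThresholdRule:
    """Median-split fallback used when EM cannot run."""
    speed_med: float
    turn_med: float

    def predict(self, X):
        lo_s = X[:, 0] <= self.speed_med
        hi_t = X[:, 1] > self.turn_med
        out = np.where(lo_s, np.where(hi_t, "LH", "LL"),
                       np.where(hi_t, "HH", "HL"))
        return out.astype(object)


class EmbcClassifier(BaseEstimator):
    """Four-state binary clustering of (speed, |turn|) by Gaussian-mixture EM.

    Variables are standardised before EM (km/h and radians are not
    commensurate); the four components are initialised at the quadrant
    centres of the per-variable medians and, after fitting, bound to
    quadrants by ordering their means: the two lowest-speed components are
    the low-speed pair, and within each pair the turn mean separates
    low-turn from high-turn. Degenerate EM solutions are retried with
    seeded jitter, then the classifier falls back to a median threshold
    rule.

    Parameters
    ----------
    max_iter, tol : EM controls.
    random_state : seed for restarts.
    n_restarts : jittered re-initialisations before falling back.
    min_points : below this many valid steps the threshold rule is used.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-6,
                 random_state: int = 0, n_restarts: int = 5,
                 min_points: int = 20):
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.n_restarts = n_restarts
        self.min_points = min_points

    # X: (n, 2) of [speed, |turn|]
    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_steps, 2): speed, |turn|")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.mean_) / self.scale_
        self.fallback_ = None
        if len(X) < self.min_points or np.any(sd == 0):
            log.warning("EMbC: %d points or zero variance; using threshold "
                        "fallback", len(X))
            self._fit_fallback(X)
            return self
        med = np.median(Z, axis=0)
        lo = [Z[Z[:, k] <= med[k], k].mean() for k in range(2)]
        hi = [Z[Z[:, k] > med[k], k].mean() for k in range(2)]
        means0 = np.array([[lo[0], lo[1]], [lo[0], hi[1]],
                           [hi[0], lo[1]], [hi[0], hi[1]]])
        rng = np.random.default_rng(self.random_state)
        for attempt in range(self.n_restarts + 1):
            init = means0 if attempt == 0 else means0 + rng.normal(0, 0.05, means0.shape)
            gm = GaussianMixture(n_components=4, covariance_type="full",
                                 means_init=init, max_iter=self.max_iter,
                                 tol=self.tol, reg_covar=1e-9,
                                 random_state=self.random_state)
            try:
                import warnings as _warnings
                with _warnings.catch_warnings():
                    # restarts are handled here; sklearn's warning is noise
                    from sklearn.exceptions import ConvergenceWarning
                    _warnings.simplefilter("ignore", ConvergenceWarning)
                    gm.fit(Z)
                if not gm.converged_ and attempt < self.n_restarts:
                    continue
                self.gmm_ = gm
                self._bind_quadrants()
                return self
            except (ValueError, np.linalg.LinAlgError):
                continue
        log.warning("EMbC: EM degenerate after %d restarts; threshold "
                    "fallback", self.n_restarts)
        self._fit_fallback(X)
        return self

    def _fit_fallback(self, X):
        self.gmm_ = None
        self.fallback_ = _ThresholdRule(float(np.median(X[:, 0])),
                                        float(np.median(X[:, 1])))
        self.delimiters_ = {"speed_kmh": self.fallback_.speed_med,
                            "turn_rad": self.fallback_.turn_med}

    def _bind_quadrants(self):
        """Map mixture components to LL/LH/HL/HH by ordering their means."""
        m = self.gmm_.means_
        order_speed = np.argsort(m[:, 0])
        low_pair, high_pair = order_speed[:2], order_speed[2:]
        comp_label = {}
        for pair, s in ((low_pair, "L"), (high_pair, "H")):
            lo_t, hi_t = pair[np.argsort(m[pair, 1])]
            comp_label[lo_t] = s + "L"
            comp_label[hi_t] = s + "H"
        self.component_label_ = np.array([comp_label[i] for i in range(4)],
                                         dtype=object)
        # delimiters on the natural scale, for reporting
        nat = m * self.scale_ + self.mean_
        self.delimiters_ = {
            "speed_kmh": float(nat[:, 0][order_speed][1:3].mean()),
            "turn_rad": float(np.sort(nat[:, 1])[1:3].mean()),
        }

    def predict(self, X):
        X = np.asarray(X, float)
        if self.fallback_ is not None:
            return self.fallback_.predict(X)
        Z = (X - self.mean_) / self.scale_
        comp = self.gmm_.predict(Z)
        return self.component_label_[comp]

    def predict_proba(self, X):
        if self.fallback_ is not None:
            raise InvalidTripError("threshold fallback has no posteriors")
        Z = (np.asarray(X, float) - self.mean_) / self.scale_
        return self.gmm_.predict_proba(Z)

    def foraging_mask(self, X) -> np.ndarray:
        return self.predict(X) == FORAGING_LABEL


def embc_classify(metrics: pd.DataFrame, max_iter: int = 200, tol: float = 1e-6,
                  seed: int = 0) -> pd.Series:
    """Label each step LL/LH/HL/HH from a `step_metrics` frame.

    Rows with undefined speed or turn get a missing label. Clustering uses
    |turn|, so mirrored tracks classify identically.
    """
    valid = metrics["speed_kmh"].notna() & metrics["turn_rad"].notna()
    X = np.column_stack([metrics.loc[valid, "speed_kmh"],
                         np.abs(metrics.loc[valid, "turn_rad"])])
    clf = EmbcClassifier(max_iter=max_iter, tol=tol, random_state=seed)
    labels = pd.Series(pd.NA, index=metrics.index, dtype=object)
    if valid.sum() == 0:
        return labels
    clf.fit(X)
    labels.loc[valid] = clf.predict(X)
    return labels


def speed_threshold_foraging(metrics_per_individual: list[pd.DataFrame]) -> list[pd.Series]:
    """Penguin rule: FORAGE iff step speed < species-pooled mean speed.

    The threshold pools every valid step of every individual of the species
    (strict inequality, so constant-speed data yields no foraging labels).
    """
    speeds = np.concatenate([m["speed_kmh"].dropna().to_numpy()
                             for m in metrics_per_individual])
    if speeds.size < 1:
        raise InvalidTripError("no steps to pool")
    threshold = float(speeds.mean())
    out = []
    for m in metrics_per_individual:
        s = m["speed_kmh"]
        lab = pd.Series(pd.NA, index=m.index, dtype=object)
        lab.loc[s.notna()] = np.where(s.dropna() < threshold, "FORAGE", "TRANSIT")
        out.append(lab)
    return out


def label_trip(trip: Trip, labels: pd.Series) -> Trip:
    """Attach behavior labels and a boolean ``foraging`` column to a trip."""
    df = trip.df.copy()
    df["label"] = labels.to_numpy()
    df["foraging"] = (labels == FORAGING_LABEL) | (labels == "FORAGE")
    return trip.with_df(df)
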