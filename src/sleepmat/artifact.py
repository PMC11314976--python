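"""Motion-artifact screening from entropy features (channel -> minute).

Body movement drives the piezoelectric sensors outside their linear
regime: bursts are non-periodic, amplified, and saturate.  Two regularity
statistics expose this per channel and component:

* energy entropy -- Shannon entropy (natural log) of the normalised
  per-window energy distribution; bursty signals concentrate energy in
  few windows and score low;
* approximate entropy (ApEn) -- Pincus' Phi_m(r) - Phi_{m+1}(r) with
  Chebyshev distance and self-matches included; irregular signals score
  high.

Six features per channel (energy entropy and ApEn of the respiratory,
BCG and deviation components) feed a 12-hidden-unit logistic MLP; a
minute is flagged when at least 7 of the 32 channels are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .decompose import DecomposedSample

#: (window, step) of the energy entropy per component, matched to the
#: component's time scale (breath ~4 s, beat ~1 s, deviation broadband)
ENERGY_ENTROPY_WINDOWS = {"resp": (400, 40), "bcg": (100, 10), "dev": (10, 1)}

#: decimation factor per component before ApEn; matched to bandwidth so the
#: regularity contrast is preserved at a fraction of the O(N*W) cost
APEN_DECIMATION = {"resp": 10, "bcg": 2, "dev": 5}

DEFAULT_CHANNEL_THRESHOLD = 7
FEATURE_NAMES = ("resp_ent_energy", "bcg_ent_energy", "dev_ent_energy",
                 "resp_ent_approx", "bcg_ent_approx", "dev_ent_approx")


def energy_entropy(x: np.ndarray, window: int, step: int) -> float:
    """Shannon entropy (nats) of the per-window energy distribution.

    Windows that would overrun the end of ``x`` are dropped; an all-zero
    signal has a degenerate distribution and scores 0.
    """
    x = np.asarray(x, dtype=float)
    if window > x.size:
        raise ValueError("window longer than the signal")
    if step < 1:
        raise ValueError("step must be >= 1")
    n_win = (x.size - window) // step + 1
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    starts = np.arange(n_win) * step
    energies = c2[starts + window] - c2[starts]
    total = energies.sum()
    if total <= 0:
        return 0.0
    p = energies / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


@njit(cache=True)
def _apen_phi(x: np.ndarray, order: np.ndarray, m: int, r: float) -> float:
    """mean_i log(C_i^m) with C_i^m the fraction of templates within
    Chebyshev distance r, counted exactly via a sorted window on the
    first coordinate (self-matches included)."""
    n = x.size - m + 1
    counts = np.zeros(n, dtype=np.int64)
    for a in range(n):
        i = order[a]
        for b in range(a, n):
            j = order[b]
            if x[j] - x[i] > r:
                break
            ok = True
            for k in range(1, m):
                d = x[i + k] - x[j + k]
                if d > r or -d > r:
                    ok = False
                    break
            if ok:
                counts[i] += 1
                if i != j:
                    counts[j] += 1
    total = 0.0
    for i in range(n):
        total += np.log(counts[i] / n)
    return total / n


def approx_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Pincus approximate entropy ApEn(m, r) with Chebyshev distance.

    ``r`` defaults to 0.2 x SD(x).  A constant series is perfectly
    regular: ApEn = 0 by definition (zero SD would make r degenerate).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.size <= m + 1:
        raise ValueError("series too short for the embedding dimension")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        return 0.0
    order_m = np.argsort(x[: x.size - m + 1], kind="stable")
    order_m1 = np.argsort(x[: x.size - m], kind="stable")
    phi_m = _apen_phi(x, order_m, m, float(r))
    phi_m1 = _apen_phi(x, order_m1, m + 1, float(r))
    return float(phi_m - phi_m1)


def approx_entropy_naive(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Brute-force O(N^2) ApEn reference (broadcast double loop)."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        return 0.0

    def phi(mm):
        n = x.size - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=-1)
        c = (d <= r).sum(axis=1) / n
        return np.log(c).mean()

    return float(phi(m) - phi(m + 1))


@dataclass(frozen=True)
class EntropyFeatureVector:
    resp_ent_energy: float
    bcg_ent_energy: float
    dev_ent_energy: float
    resp_ent_approx: float
    bcg_ent_approx: float
    dev_ent_approx: float

    def as_array(self) -> np.ndarray:
        return np.array([self.resp_ent_energy, self.bcg_ent_energy,
                         self.dev_ent_energy, self.resp_ent_approx,
                         self.bcg_ent_approx, self.dev_ent_approx])


def channel_features(d: DecomposedSample, channel: int) -> EntropyFeatureVector:
    """Six entropy features of one channel, ordered energy-entropies first."""
    if not 0 <= channel < d.resp.shape[0]:
        raise ValueError("channel index out of range")
    comps = {"resp": d.resp[channel], "bcg": d.bcg[channel], "dev": d.dev[channel]}
    ee = {k: energy_entropy(v, *ENERGY_ENTROPY_WINDOWS[k]) for k, v in comps.items()}
    ae = {k: approx_entropy(v[:: APEN_DECIMATION[k]]) for k, v in comps.items()}
    return EntropyFeatureVector(ee["resp"], ee["bcg"], ee["dev"],
                                ae["resp"], ae["bcg"], ae["dev"])


def sample_features(d: DecomposedSample) -> np.ndarray:
    """(32, 6) feature matrix for a whole minute."""
    return np.stack([channel_features(d, c).as_array()
                     for c in range(d.resp.shape[0])])


@dataclass
class ArtifactDecision:
    channel_flags: np.ndarray
    interfered_count: int
    sample_flag: bool


def flag_sample(channel_flags: np.ndarray,
                threshold: int = DEFAULT_CHANNEL_THRESHOLD) -> ArtifactDecision:
    """A minute is interfered when >= ``threshold`` channels are flagged."""
    channel_flags = np.asarray(channel_flags, dtype=bool)
    if channel_flags.shape != (32,):
        raise ValueError("expected exactly 32 channel flags")
    count = int(channel_flags.sum())
    return ArtifactDecision(channel_flags, count, count >= threshold)


class ArtifactDetector:
    """Channel-level MLP (12 logistic hidden units) plus the 7-channel rule.

    sklearn-style estimator: ``fit`` on pooled (channel-minute) entropy
    features with boolean interference labels; ``predict_channels`` yields
    per-channel flags at the 0.5 posterior threshold; ``predict_minutes``
    applies the counting rule.
    """

    def __init__(self, threshold: int = DEFAULT_CHANNEL_THRESHOLD,
                 random_state: int = 0, max_iter: int = 500):
        self.threshold = threshold
        self.random_state = random_state
        self.max_iter = max_iter

    def get_params(self, deep=True):
        return {"threshold": self.threshold, "random_state": self.random_state,
                "max_iter": self.max_iter}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present to train")
        # z-score the entropy features (their natural scales span 0.2-8
        # nats) and stop on a training-loss plateau
        self.scaler_ = StandardScaler().fit(X)
        self.mlp_ = MLPClassifier(hidden_layer_sizes=(12,), activation="logistic",
                                  max_iter=self.max_iter, n_iter_no_change=20,
                                  tol=1e-5, random_state=self.random_state)
        self.mlp_.fit(self.scaler_.transform(X), y.astype(int))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = self.scaler_.transform(np.asarray(X, dtype=float))
        return self.mlp_.predict_proba(X)

    def predict(self, X):
        """Channel flags: posterior of the interfered class > 0.5."""
        return self.predict_proba(X)[:, 1] > 0.5

    predict_channels = predict

    def decide(self, channel_feature_matrix: np.ndarray) -> ArtifactDecision:
        """Flag one minute from its (32, 6) feature matrix."""
        flags = self.predict(channel_feature_matrix)
        return flag_sample(flags, self.threshold)

    def predict_minutes(self, per_minute_features) -> np.ndarray:
        """Boolean minute flags for an iterable of (32, 6) matrices."""
        return np.array([self.decide(f).sample_flag for f in per_minute_features])


def train_artifact_mlp(features, labels, seed: int = 0) -> ArtifactDetector:
    """Thin functional wrapper over :class:`ArtifactDetector`."""
    X = np.stack([f.as_array() if isinstance(f, EntropyFeatureVector) else np.asarray(f)
                  for f in features])
    return ArtifactDetector(random_state=seed).fit(X, labels)
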