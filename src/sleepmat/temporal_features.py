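"""Temporal amplitude/interval features of respiration and heartbeat.

Per minute, one respiratory series and one BCG series (energy-weighted
channel aggregates) are reduced to peak trains: the respiratory trace is
smoothed (moving average, window 5) and peaks are located between upward
zero crossings; the BCG trace is envelope-detected first, then treated
the same way.  Each train is expanded back to a uniform 2 x 6000 series
by piecewise-constant interpolation -- between consecutive peaks the
amplitude row repeats the left peak's amplitude and the interval row
repeats that gap in seconds -- and finally resampled to the network sizes
(2 x 90 for respiration, 2 x 180 for heartbeat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decompose import DecomposedSample
from .spatial_features import envelope
from .synthdata import FS, MINUTE_SAMPLES

RESP_TARGET = 90
BCG_TARGET = 180

#: plausibility bounds on inter-event gaps (seconds): 6-48 breaths/min,
#: 48-180 beats/min
RESP_INTERVAL_RANGE = (1.25, 10.0)
BEAT_INTERVAL_RANGE = (0.33, 1.25)


class UnusableMinuteError(ValueError):
    """No usable peak train could be extracted from this minute."""


@dataclass
class PeakTrain:
    indices: np.ndarray      # strictly increasing sample positions
    amplitudes: np.ndarray
    fs: float = FS

    @property
    def intervals(self) -> np.ndarray:
        """Successor gaps in samples (one fewer than the peaks)."""
        return np.diff(self.indices)

    def __len__(self):
        return self.indices.size


@dataclass
class TemporalFeatureSet:
    M1: np.ndarray           # 2 x 90: respiration amplitudes / intervals (s)
    M2: np.ndarray           # 2 x 180: heartbeat amplitudes / intervals (s)


def moving_average(x: np.ndarray, w: int = 5) -> np.ndarray:
    """Centred mean with reflected edges; length preserved."""
    x = np.asarray(x, dtype=float)
    if w % 2 == 0:
        raise ValueError("window must be odd")
    if w > x.size:
        raise ValueError("window longer than the signal")
    half = w // 2
    xp = np.concatenate([x[half:0:-1], x, x[-2:-half - 2:-1]])
    kernel = np.full(w, 1.0 / w)
    return np.convolve(xp, kernel, mode="valid")


def zero_crossing_peaks(x: np.ndarray, fs: float = FS) -> PeakTrain:
    """One peak per positive half-cycle opened by an upward zero crossing.

    Each upward crossing starts a half-cycle whose peak is the maximum
    up to the next crossing (or the end of the signal); half-cycles
    already open at the start, or cut off at the end, of the record are
    included.  Half-cycles much shorter than typical (< 20% of the
    median span) are discarded as crossing artifacts -- residual spikes
    near a zero crossing would otherwise split a breath or fabricate
    one.
    """
    x = np.asarray(x, dtype=float)
    pos = x > 0
    up = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
    if up.size < 2:
        return PeakTrain(np.array([], dtype=int), np.array([]), fs)
    bounds = np.append(up, x.size)
    if np.any(x[:up[0]] > 0):          # half-cycle already open at start
        bounds = np.insert(bounds, 0, 0)
    idx, amps, spans = [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = x[a:b]
        k = int(np.argmax(seg))
        if seg[k] > 0:
            idx.append(a + k)
            amps.append(seg[k])
            spans.append(b - a)
    spans = np.asarray(spans, dtype=float)
    keep = np.ones(spans.size, dtype=bool)
    if spans.size > 2:
        keep = spans >= 0.2 * np.median(spans)
    return PeakTrain(np.asarray(idx, dtype=int)[keep],
                     np.asarray(amps)[keep], fs)


def peak_series(train: PeakTrain, length: int = MINUTE_SAMPLES) -> np.ndarray:
    """Piecewise-constant 2 x length expansion of a peak train.

    Row 0 holds amplitudes, row 1 the inter-peak interval in seconds;
    before the first and after the last peak the nearest value is held.
    """
    if len(train) < 2:
        raise UnusableMinuteError("need at least two peaks to expand")
    out = np.empty((2, length))
    gaps_s = train.intervals / train.fs
    bounds = np.clip(train.indices, 0, length)
    out[0, : bounds[0]] = train.amplitudes[0]
    out[1, : bounds[0]] = gaps_s[0]
    for i in range(len(train) - 1):
        a, b = bounds[i], bounds[i + 1]
        out[0, a:b] = train.amplitudes[i]
        out[1, a:b] = gaps_s[i]
    out[0, bounds[-1]:] = train.amplitudes[-1]
    out[1, bounds[-1]:] = gaps_s[-1]
    return out


def resample_features(series: np.ndarray, target: int) -> np.ndarray:
    """Linear interpolation of each row at ``target`` uniform points."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if target <= 0:
        raise ValueError("target length must be positive")
    n = series.shape[1]
    xq = np.linspace(0.0, n - 1.0, target)
    return np.stack([np.interp(xq, np.arange(n), row) for row in series])


def _aggregate(components: np.ndarray, energies: np.ndarray) -> np.ndarray:
    w = np.maximum(np.asarray(energies, dtype=float), 0.0)
    if w.sum() <= 0:
        raise UnusableMinuteError("zero-energy minute")
    return (w[:, None] * components).sum(axis=0) / w.sum()


def extract_temporal(d: DecomposedSample, smooth_window: int = 5) -> TemporalFeatureSet:
    """Temporal feature matrices (2 x 90 and 2 x 180) of one clean minute."""
    resp = _aggregate(d.resp, d.resp_energy)
    bcg = _aggregate(d.bcg, d.bcg_energy)
    if not (np.any(resp) and np.any(bcg)):
        raise UnusableMinuteError("zero-variance minute")

    resp_train = zero_crossing_peaks(moving_average(resp, smooth_window))
    env = envelope(bcg)
    beat_train = zero_crossing_peaks(env - env.mean())
    try:
        m1 = resample_features(peak_series(resp_train), RESP_TARGET)
        m2 = resample_features(peak_series(beat_train), BCG_TARGET)
    except UnusableMinuteError as err:
        raise UnusableMinuteError(f"minute has no usable peaks: {err}") from err
    return TemporalFeatureSet(M1=m1, M2=m2)


class TemporalFeatureExtractor:
    """sklearn-style transformer: DecomposedSample -> TemporalFeatureSet."""

    def __init__(self, smooth_window: int = 5):
        self.smooth_window = smooth_window

    def get_params(self, deep=True):
        return {"smooth_window": self.smooth_window}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        return [extract_temporal(d, self.smooth_window) for d in X]
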