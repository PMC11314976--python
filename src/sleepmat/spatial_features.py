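"""Model-based spatial features: cardiorespiratory activity intensity maps.

The decomposed respiratory component is well described by a single
sinusoid ``A_res sin(2 pi f_res t + phi)``; the BCG component by an
amplitude-modulated carrier ``U_Am (1 + M cos(2 pi f_hea t + phi_h))
cos(2 pi f_bcg t + phi_c)`` whose envelope tracks the heartbeat and whose
carrier runs near five times the heart rate (five IJKL waves per beat).

Per-channel driving-force intensities are recovered without any fit via
the total-variation identity of a sinusoid -- the summed absolute
first difference of ``A sin(2 pi f t)`` over N samples is ``4 A f N dt``
(4A per cycle) -- inverted through the sensor transfer ``U = beta d33 /
CM * F``.  The 32 intensities form a 4 x 8 grid which is bicubically
upsampled to 16 x 32 and lightly smoothed for the CNN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy import signal as sps

from .decompose import DecomposedSample
from .synthdata import FS, GRID_SHAPE, PiezoParams, voltage_to_force

RESP_FREQ_RANGE = (0.1, 0.8)
HEART_FREQ_RANGE = (0.8, 3.0)
CARRIER_FREQ_RANGE = (3.0, 15.0)
UPSAMPLE_FACTOR = 4
MAP_SHAPE = (16, 32)


class RejectedFitError(ValueError):
    """The dominant frequency fell outside the physiological band."""


@dataclass
class RespFit:
    Ares: float
    fres: float
    phase: float
    r_squared: float


@dataclass
class BcgFit:
    UAm: float
    Mbcg: float
    fhea: float
    fbcg: float
    r_squared: float


@dataclass
class IntensityMapPair:
    fres_map: np.ndarray        # 4 x 8 respiratory intensity
    fbcg_map: np.ndarray        # 4 x 8 cardiac intensity
    upsampled_resp: np.ndarray  # 16 x 32
    upsampled_bcg: np.ndarray   # 16 x 32


def _dft_peak(x: np.ndarray, fs: float, band: tuple[float, float],
              reject_outside: bool = False) -> float:
    """Dominant in-band frequency with parabolic sub-bin interpolation.

    With ``reject_outside`` the *global* spectral maximum must itself lie
    inside the band, otherwise the minute is rejected -- the component is
    then not the physiological signal the model assumes.
    """
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any() or not np.any(spec[mask] > 0):
        raise RejectedFitError(f"no spectral peak inside {band} Hz")
    if reject_outside:
        f_glob = freqs[1 + np.argmax(spec[1:])]
        if not band[0] <= f_glob <= band[1]:
            raise RejectedFitError(
                f"dominant frequency {f_glob:.3f} Hz outside {band} Hz")
    idx = np.flatnonzero(mask)[np.argmax(spec[mask])]
    if 0 < idx < spec.size - 1:
        a, b, c = spec[idx - 1], spec[idx], spec[idx + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float(freqs[idx] + delta * (freqs[1] - freqs[0]))


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def _sinusoid_lstsq(y: np.ndarray, f: float, fs: float):
    """Least-squares amplitude/phase of a sinusoid at fixed frequency."""
    t = np.arange(y.size) / fs
    basis = np.column_stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    amp = float(np.hypot(*coef))
    phase = float(np.arctan2(coef[1], coef[0]))
    return amp, phase, basis @ coef


def fit_respiration(resp: np.ndarray, fs: float = FS) -> RespFit:
    """Single-sinusoid least-squares fit to a one-minute respiratory trace.

    The frequency is initialised at the in-band DFT peak and refined by a
    local grid around it (+-1 DFT bin); amplitude and phase are solved
    linearly at each candidate.
    """
    resp = np.asarray(resp, dtype=float)
    f0 = _dft_peak(resp, fs, RESP_FREQ_RANGE, reject_outside=True)
    bin_w = fs / resp.size
    best = None
    for f in np.linspace(f0 - bin_w, f0 + bin_w, 21):
        if f <= 0:
            continue
        amp, phase, yhat = _sinusoid_lstsq(resp, f, fs)
        r2 = _r_squared(resp, yhat)
        if best is None or r2 > best[0]:
            best = (r2, amp, f, phase)
    r2, amp, f, phase = best
    return RespFit(Ares=amp, fres=f, phase=phase, r_squared=r2)


def envelope(x: np.ndarray, fs: float = FS, cutoff_hz: float = 3.0) -> np.ndarray:
    """Amplitude envelope: analytic-signal magnitude, low-pass smoothed.

    Smoothing uses a forward-backward 4th-order Butterworth at 3 Hz so the
    heartbeat-rate modulation survives while carrier ripple is removed.
    Nonnegative, same length as the input.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if not np.any(x):
        return np.zeros_like(x)
    env = np.abs(sps.hilbert(x))
    sos = sps.butter(4, cutoff_hz, fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, env)
    return np.maximum(env, 0.0)


def fit_bcg_am(bcg: np.ndarray, fs: float = FS) -> BcgFit:
    """Fit the AM heartbeat model to a one-minute BCG trace.

    Heart rate comes from the DFT peak of the (mean-removed) envelope,
    the carrier from the DFT peak of the raw trace.  A linear three-cosine
    fit (carrier plus the two sidebands, free phases) seeds a constrained
    nonlinear refinement of the AM form.
    """
    bcg = np.asarray(bcg, dtype=float)
    env = envelope(bcg, fs)
    fhea = _dft_peak(env, fs, HEART_FREQ_RANGE, reject_outside=True)
    fbcg = _dft_peak(bcg, fs, CARRIER_FREQ_RANGE)
    t = np.arange(bcg.size) / fs

    def cols(f):
        return [np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)]

    basis = np.column_stack(cols(fbcg) + cols(fbcg - fhea) + cols(fbcg + fhea))
    coef, *_ = np.linalg.lstsq(basis, bcg, rcond=None)
    uam = float(np.hypot(coef[0], coef[1]))
    side = float(np.hypot(coef[2], coef[3]) + np.hypot(coef[4], coef[5]))
    m0 = float(np.clip(side / uam if uam > 0 else 0.5, 0.05, 0.99))
    phi_c0 = float(np.arctan2(-coef[1], coef[0]))

    def model(p):
        uam_, m_, fh_, fc_, ph_, pc_ = p
        return uam_ * (1 + m_ * np.cos(2 * np.pi * fh_ * t + ph_)) * \
            np.cos(2 * np.pi * fc_ * t + pc_)

    p0 = np.array([uam, m0, fhea, fbcg, 0.0, phi_c0])
    res = optimize.least_squares(
        lambda p: model(p) - bcg, p0,
        bounds=([0, 0, fhea * 0.95, fbcg * 0.98, -np.pi, -np.pi],
                [np.inf, 1, fhea * 1.05, fbcg * 1.02, np.pi, np.pi]),
        max_nfev=60)
    uam_f, m_f, fh_f, fc_f = res.x[:4]
    r2 = _r_squared(bcg, model(res.x))
    return BcgFit(UAm=float(uam_f), Mbcg=float(m_f), fhea=float(fh_f),
                  fbcg=float(fc_f), r_squared=float(r2))


def total_variation(x: np.ndarray) -> float:
    """Sum of absolute first differences."""
    return float(np.abs(np.diff(np.asarray(x, dtype=float))).sum())


def estimate_intensity(component: np.ndarray, f: float,
                       params: PiezoParams | None = None,
                       kind: str = "resp", mbcg: float | None = None) -> float:
    """Driving-force intensity of one channel from summed variation.

    A sinusoid of amplitude A at frequency f accumulates |dU| = 4 A per
    cycle, so over N samples the effective amplitude is
    ``sum|dU| / (4 f N dt)``.  The voltage amplitude is converted to force
    through the inverse sensor transfer.  For ``kind='bcg_envelope'`` the
    input is the envelope series, whose oscillating part has amplitude
    ``U_Am * M``; the intensity then additionally divides by the
    separately estimated modulation index ``mbcg``.
    """
    if f <= 0:
        raise ValueError("characteristic frequency must be positive")
    if kind not in ("resp", "bcg_envelope"):
        raise ValueError("kind must be 'resp' or 'bcg_envelope'")
    params = params or PiezoParams()
    x = np.asarray(component, dtype=float)
    n = x.size
    amp = total_variation(x) / (4.0 * f * n * params.dt)
    if kind == "bcg_envelope":
        amp = amp / (mbcg if mbcg else 1.0)
    return voltage_to_force(amp, params)


def build_maps(per_channel_resp_intensity: np.ndarray,
               per_channel_bcg_intensity: np.ndarray,
               smooth_sigma: float = 1.0) -> IntensityMapPair:
    """Upsample the 4 x 8 intensity grids fourfold (bicubic) and smooth.

    Bicubic interpolation can overshoot below zero between grid points;
    negative values are clipped.  Smoothing is Gaussian with sigma of one
    upsampled grid unit.
    """
    maps = []
    for grid in (per_channel_resp_intensity, per_channel_bcg_intensity):
        grid = np.asarray(grid, dtype=float)
        if grid.shape != GRID_SHAPE:
            raise ValueError("intensity grid must be 4 x 8")
        if not np.isfinite(grid).all() or (grid < 0).any():
            raise ValueError("intensities must be finite and nonnegative")
        up = ndimage.zoom(grid, UPSAMPLE_FACTOR, order=3, mode="nearest",
                          grid_mode=True)
        up = np.maximum(up, 0.0)
        if smooth_sigma > 0:
            up = ndimage.gaussian_filter(up, smooth_sigma, mode="nearest")
        maps.append(up)
    return IntensityMapPair(np.asarray(per_channel_resp_intensity, dtype=float),
                            np.asarray(per_channel_bcg_intensity, dtype=float),
                            maps[0], maps[1])


def extract_spatial(d: DecomposedSample,
                    params: PiezoParams | None = None) -> IntensityMapPair:
    """Full spatial pathway for one uninterfered minute.

    Characteristic frequencies are estimated once from the energy-weighted
    channel aggregate; per-channel intensities then come from each
    channel's own summed variation.
    """
    params = params or PiezoParams()
    w_r = np.maximum(d.resp_energy, 0)
    w_b = np.maximum(d.bcg_energy, 0)
    agg_resp = (w_r[:, None] * d.resp).sum(axis=0) / max(w_r.sum(), 1e-30)
    agg_bcg = (w_b[:, None] * d.bcg).sum(axis=0) / max(w_b.sum(), 1e-30)
    fres = _dft_peak(agg_resp, FS, RESP_FREQ_RANGE)
    env_agg = envelope(agg_bcg, FS)
    fhea = _dft_peak(env_agg, FS, HEART_FREQ_RANGE)
    mfit = fit_bcg_am(agg_bcg, FS)
    resp_int = np.array([estimate_intensity(ch, fres, params, "resp")
                         for ch in d.resp]).reshape(GRID_SHAPE)
    bcg_int = np.array([estimate_intensity(envelope(ch, FS), fhea, params,
                                           "bcg_envelope", mbcg=mfit.Mbcg)
                        for ch in d.bcg]).reshape(GRID_SHAPE)
    return build_maps(resp_int, bcg_int)


def normalized_map_stack(pair: IntensityMapPair) -> tuple[np.ndarray, np.ndarray]:
    """Per-map max normalisation of the two upsampled maps (CNN input)."""
    out = []
    for m in (pair.upsampled_resp, pair.upsampled_bcg):
        mx = m.max()
        out.append(m / mx if mx > 0 else m.copy())
    return out[0], out[1]


class SpatialFeatureExtractor:
    """sklearn-style transformer: DecomposedSample -> IntensityMapPair."""

    def __init__(self, params: PiezoParams | None = None):
        self.params = params or PiezoParams()

    def get_params(self, deep=True):
        return {"params": self.params}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        return [extract_spatial(d, self.params) for d in X]
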