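"""Band decomposition of mat signals into respiratory / BCG / deviation parts.

Each one-minute channel is split with two linear-phase FIR band-pass
filters (0.1-0.8 Hz respiration, 0.8-15 Hz ballistocardiogram); the
deviation component is the pointwise remainder.  Band energies are sums
of squares; the deviation energy is defined as the residual
``composite - (resp + bcg)`` energy, which can differ slightly from the
energy of the deviation signal itself because the components are not
exactly orthogonal over a finite window.

The filters are 1000-tap (order 999) Dolph-Chebyshev-window designs built
as the difference of two DC-normalised low-passes, which places an exact
null at DC.  Filtering is a single pass over a reflection-padded signal
with the group delay (order/2 samples) removed, so component peaks stay
time-aligned with the composite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthdata import FS, MinuteSample, N_CHANNELS

RESP_BAND = (0.1, 0.8)
BCG_BAND = (0.8, 15.0)
DEFAULT_ORDER = 999
# Sidelobe attenuation of the Dolph-Chebyshev window.  42 dB keeps the
# passband flat to ~0.15 dB at 0.25 Hz (droop moves respiratory energy into
# the residual, because the deviation energy is defined as a residual) while
# still holding > 40 dB an octave above the respiratory band.
_CHEB_ATTEN_DB = 42.0


@dataclass(frozen=True)
class FilterSpec:
    low_hz: float
    high_hz: float
    order: int = DEFAULT_ORDER
    fs: float = FS

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz < self.fs / 2:
            raise ValueError("need 0 < low < high < Nyquist")
        if self.order < 2:
            raise ValueError("order must be at least 2")


RESP_SPEC = FilterSpec(*RESP_BAND)
BCG_SPEC = FilterSpec(*BCG_BAND)


def design_fir_bandpass(spec: FilterSpec) -> np.ndarray:
    """Symmetric (order+1)-tap band-pass as a difference of two
    Chebyshev-window low-passes with exactly unit DC gain each."""
    numtaps = spec.order + 1
    win = ("chebwin", _CHEB_ATTEN_DB)
    with warnings.catch_warnings():
        # scipy warns that chebwin < 45 dB is unsuitable as a *spectral
        # analysis* window (non-monotone noise bandwidth); irrelevant here.
        warnings.simplefilter("ignore", UserWarning)
        h_hi = sps.firwin(numtaps, spec.high_hz, window=win, fs=spec.fs)
        h_lo = sps.firwin(numtaps, spec.low_hz, window=win, fs=spec.fs)
    return h_hi - h_lo


def frequency_response(coeffs: np.ndarray, freqs, fs: float = FS) -> np.ndarray:
    """|H(f)| evaluated directly from the coefficient vector."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    n = np.arange(len(coeffs))
    z = np.exp(-2j * np.pi * np.outer(freqs / fs, n))
    return np.abs(z @ coeffs)


def apply_fir(x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR along the last axis with odd-reflection
    padding (point symmetry about the endpoints, as in filtfilt) and
    group-delay compensation; output has the input's length.  Odd
    reflection continues an oscillation with matching value and slope,
    keeping edge transients small."""
    x = np.asarray(x, dtype=float)
    ntaps = len(coeffs)
    if x.shape[-1] < ntaps:
        raise ValueError("signal shorter than the filter")
    pad = ntaps // 2
    left = 2.0 * x[..., :1] - x[..., pad:0:-1]
    right = 2.0 * x[..., -1:] - x[..., -2:-pad - 2:-1]
    xp = np.concatenate([left, x, right], axis=-1)
    y = sps.fftconvolve(xp, coeffs[None, :] if x.ndim == 2 else coeffs,
                        mode="same", axes=-1)
    return y[..., pad:pad + x.shape[-1]]


@dataclass
class DecomposedSample:
    """Per-channel components and band energies of one minute."""

    resp: np.ndarray
    bcg: np.ndarray
    dev: np.ndarray
    composite_energy: np.ndarray
    resp_energy: np.ndarray
    bcg_energy: np.ndarray
    dev_energy: np.ndarray          # residual definition, may dip below 0
    posture: str | None = None
    movement: bool | None = None
    per_channel_movement: np.ndarray | None = None

    @property
    def resp_fraction(self) -> np.ndarray:
        return self.resp_energy / self.composite_energy

    @property
    def bcg_fraction(self) -> np.ndarray:
        return self.bcg_energy / self.composite_energy

    @property
    def dev_fraction(self) -> np.ndarray:
        return self.dev_energy / self.composite_energy


def decompose_minute(sample: MinuteSample | np.ndarray,
                     resp_filter: np.ndarray | None = None,
                     bcg_filter: np.ndarray | None = None) -> DecomposedSample:
    """Split a 32 x N minute into components and compute band energies."""
    if resp_filter is None:
        resp_filter = design_fir_bandpass(RESP_SPEC)
    if bcg_filter is None:
        bcg_filter = design_fir_bandpass(BCG_SPEC)
    if isinstance(sample, MinuteSample):
        x = sample.voltages
        meta = dict(posture=sample.posture, movement=sample.movement,
                    per_channel_movement=sample.per_channel_movement)
    else:
        x = np.asarray(sample, dtype=float)
        meta = {}
    resp = apply_fir(x, resp_filter)
    bcg = apply_fir(x, bcg_filter)
    dev = x - (resp + bcg)
    comp_e = np.sum(x**2, axis=-1)
    resp_e = np.sum(resp**2, axis=-1)
    bcg_e = np.sum(bcg**2, axis=-1)
    dev_e = comp_e - (resp_e + bcg_e)
    return DecomposedSample(resp, bcg, dev, comp_e, resp_e, bcg_e, dev_e, **meta)


class BandpassDecomposer:
    """Stateless sklearn-style transformer over minute samples.

    ``transform`` maps a list of :class:`MinuteSample` (or bare 32 x 6000
    arrays) to a list of :class:`DecomposedSample`.  Filters are designed
    once at construction.
    """

    def __init__(self, resp_spec: FilterSpec = RESP_SPEC,
                 bcg_spec: FilterSpec = BCG_SPEC):
        self.resp_spec = resp_spec
        self.bcg_spec = bcg_spec
        self._resp_fir = design_fir_bandpass(resp_spec)
        self._bcg_fir = design_fir_bandpass(bcg_spec)

    def get_params(self, deep=True):
        return {"resp_spec": self.resp_spec, "bcg_spec": self.bcg_spec}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        self._resp_fir = design_fir_bandpass(self.resp_spec)
        self._bcg_fir = design_fir_bandpass(self.bcg_spec)
        return self

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        return [decompose_minute(x, self._resp_fir, self._bcg_fir) for x in X]
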