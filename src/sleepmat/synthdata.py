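"""Synthetic piezoelectric-mat recordings of sleeping subjects.

The real mat is a 4 x 8 grid of piezoelectric ceramic sensors sampled at
100 Hz near the chest.  Each one-minute sample mixes three sources per
channel:

* respiration -- a jittered sinusoid in the 0.1-0.8 Hz band,
* the ballistocardiogram (BCG) -- an amplitude-modulated carrier whose
  envelope follows the heart rate and whose carrier runs at five times
  the heart rate (five IJKL waves per beat),
* deviation noise -- broadband, body-coupled background.

Body movement contaminates a minute with saturating broadband bursts on
at least seven channels.  Posture (supine / right-lateral / left-lateral)
enters through fixed spatial coupling templates on the sensor grid and
through mild physiological modulation.

Grid convention (used everywhere in the package): 4 rows x 8 columns,
row-major channel indexing, column index increasing toward the subject's
left.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FS = 100.0
MINUTE_SAMPLES = 6000
GRID_SHAPE = (4, 8)
N_CHANNELS = 32
POSTURES = ("supine", "right_lateral", "left_lateral")
#: long-run fraction of night time spent in each posture
POSTURE_MIX = {"supine": 0.4978, "right_lateral": 0.3356, "left_lateral": 0.1666}

#: population-level physiological modulation by posture.  Supine breathing
#: is slower and deeper (greater diaphragm excursion against the mat);
#: lying on the left brings the heart closer to the mat (stronger BCG
#: coupling) and lateral decubitus shifts heart rate slightly in opposite
#: directions for the two sides.
POSTURE_MODULATION = {
    "supine": {"fres": 0.88, "resp_amp": 1.25, "fhea": 1.00, "bcg_amp": 1.00},
    "right_lateral": {"fres": 1.10, "resp_amp": 0.75, "fhea": 1.06, "bcg_amp": 0.80},
    "left_lateral": {"fres": 1.10, "resp_amp": 0.75, "fhea": 0.94, "bcg_amp": 1.20},
}


@dataclass(frozen=True)
class PiezoParams:
    """Electrical constants of one sensor channel and its amplifier.

    ``d33`` is the piezoelectric charge constant (C/N), ``beta`` the
    amplifier gain, ``RM``/``CM`` the equivalent input resistance (ohm) and
    capacitance (F) of the amplifying circuit.  Voltage units downstream
    are arbitrary (normalised), but the constants fix the force-to-voltage
    scale used when activity intensities are recovered.
    """

    d33: float = 200e-12
    beta: float = 100.0
    RM: float = 1e7
    CM: float = 1e-8
    fs: float = FS

    def __post_init__(self):
        if not 0 < self.d33 <= 600e-12:
            raise ValueError("d33 must be in (0, 600e-12] C/N")
        if min(self.beta, self.RM, self.CM, self.fs) <= 0:
            raise ValueError("beta, RM, CM, fs must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.fs


@dataclass
class SubjectProfile:
    """Per-subject physiology driving the generator."""

    subject_id: str = "s00"
    fres: float = 0.25          # respiration frequency, Hz
    fhea: float = 1.2           # heart rate, Hz
    resp_amp: float = 1.0       # respiration voltage amplitude (arb. units)
    bcg_amp: float = 0.26       # BCG carrier amplitude U_Am
    mbcg: float = 0.4           # AM modulation index
    freq_jitter_sd: float = 0.01   # per-cycle relative frequency jitter
    amp_jitter_sd: float = 0.05    # per-cycle relative amplitude jitter
    noise_sd: float = 0.12      # deviation-noise SD at a full-weight channel
    movement_rate: float = 0.11  # fraction of contaminated minutes

    def __post_init__(self):
        if not 0.1 <= self.fres <= 0.8:
            raise ValueError("fres must lie in the respiratory band 0.1-0.8 Hz")
        if not 0.8 <= self.fhea <= 3.0:
            raise ValueError("fhea must lie in 0.8-3 Hz (carrier 5*fhea <= 15 Hz)")
        if not 0 < self.mbcg < 1:
            raise ValueError("modulation index must be in (0, 1)")
        if not 0 <= self.movement_rate < 1:
            raise ValueError("movement_rate must be in [0, 1)")


@dataclass(frozen=True)
class SpatialTemplate:
    """Posture-specific coupling weights on the 4 x 8 grid (max = 1)."""

    posture: str
    resp_weights: np.ndarray
    bcg_weights: np.ndarray

    def __post_init__(self):
        for w in (self.resp_weights, self.bcg_weights):
            if w.shape != GRID_SHAPE or (w < 0).any():
                raise ValueError("weights must be a nonnegative 4x8 grid")


@dataclass
class PostureSchedule:
    """Ordered (posture, duration-in-minutes) segments of one night."""

    segments: list[tuple[str, int]]

    @property
    def total_minutes(self) -> int:
        return sum(d for _, d in self.segments)

    @property
    def n_changes(self) -> int:
        return len(self.segments) - 1

    def minute_labels(self) -> list[str]:
        out: list[str] = []
        for posture, dur in self.segments:
            out.extend([posture] * dur)
        return out


@dataclass
class MinuteSample:
    """One minute of 32-channel voltage plus generator ground truth."""

    voltages: np.ndarray                 # (32, 6000)
    posture: str
    movement: bool
    per_channel_movement: np.ndarray     # (32,) bool

    def __post_init__(self):
        if self.voltages.shape != (N_CHANNELS, MINUTE_SAMPLES):
            raise ValueError("voltages must be 32 x 6000")
        if not np.isfinite(self.voltages).all():
            raise ValueError("voltages must be finite")


def sensor_transfer(Fm: float, omega: float, params: PiezoParams) -> float:
    """Voltage amplitude produced by a sinusoidal force of amplitude ``Fm``.

    U = d33 * Fm * omega * RM * beta / sqrt(1 + (omega RM CM)^2); in the
    high-frequency regime (omega RM CM >> 1) this saturates at
    beta * d33 * Fm / CM, the linear operating range of the mat.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if Fm < 0:
        raise ValueError("force amplitude must be nonnegative")
    wrc = omega * params.RM * params.CM
    return params.d33 * Fm * omega * params.RM * params.beta / np.sqrt(1.0 + wrc**2)


def voltage_to_force(amplitude: float, params: PiezoParams) -> float:
    """Invert the high-frequency transfer: F = U * CM / (beta * d33)."""
    return amplitude * params.CM / (params.beta * params.d33)


# ---------------------------------------------------------------------------
# spatial templates

_ROWS, _COLS = np.meshgrid(np.arange(4), np.arange(8), indexing="ij")


def _gauss(rc, cc, sr, sc, a=1.0):
    return a * np.exp(-0.5 * (((_ROWS - rc) / sr) ** 2 + ((_COLS - cc) / sc) ** 2))


def _norm(w, floor=0.05):
    w = w / w.max()
    return np.maximum(w, floor)


def make_template(posture: str, col_shift: float = 0.0,
                  row_shift: float = 0.0) -> SpatialTemplate:
    """Coupling template for a posture, optionally shifted on the grid.

    Supine: broad thoracic contact; cardiac map slightly toward the
    subject's left.  Lateral: a narrow high-intensity contact ridge on the
    supporting side with a broad low-intensity counterweight on the other
    side, so the weight centroid falls on the opposite side of the grid
    midline from the maximum (static moment balance: the body tilts
    opposite to the centre-of-gravity offset).  ``col_shift``/``row_shift``
    translate all lobe centres (body position on the mat, in grid units).
    """
    c, r = col_shift, row_shift
    if posture == "supine":
        resp = _norm(_gauss(1.5 + r, 3.5 + c, 1.8, 2.8))
        bcg = _norm(_gauss(1.5 + r, 4.2 + c, 1.5, 2.3))
    elif posture == "right_lateral":
        resp = _norm(_gauss(1.5 + r, 0.8 + c, 1.6, 0.75) +
                     _gauss(1.5 + r, 6.3 + c, 2.0, 2.7, 0.74))
        bcg = _norm(_gauss(1.5 + r, 1.0 + c, 1.4, 0.70) +
                    _gauss(1.5 + r, 6.2 + c, 1.9, 2.5, 0.72))
    elif posture == "left_lateral":
        base = make_template("right_lateral", col_shift=-c, row_shift=r)
        resp, bcg = base.resp_weights[:, ::-1], base.bcg_weights[:, ::-1]
    else:
        raise ValueError(f"unknown posture {posture!r}")
    return SpatialTemplate(posture, np.ascontiguousarray(resp), np.ascontiguousarray(bcg))


def subject_template(posture: str, rng: np.random.Generator,
                     weight_sd: float = 0.35, col_shift_sd: float = 0.6,
                     row_shift_sd: float = 0.35) -> SpatialTemplate:
    """Subject-level anatomical variation of a posture template.

    Beyond translating the lobe centres (body position on the mat), the
    lobe *structure* is drawn per subject: contact widths scale with
    build, the lateral counterweight varies from faint to strong, and
    supine sleepers may carry a lateral tilt that makes their map
    partially resemble a lateral one.  Per-channel coupling gets
    lognormal jitter (local contact quality).  The diversity is
    calibrated so that posture classification from maps of *unseen*
    subjects is good but imperfect, as observed on real mats, rather
    than trivially separable.
    """
    c = float(np.clip(rng.normal(0.0, col_shift_sd), -1.5, 1.5))
    r = float(np.clip(rng.normal(0.0, row_shift_sd), -0.8, 0.8))
    wide = float(rng.lognormal(0.0, 0.22))        # body build
    if posture == "supine":
        tilt = float(rng.uniform(0.0, 0.45))      # partial lateral tilt
        side = 1.0 if rng.random() < 0.5 else 6.2
        resp = _gauss(1.5 + r, 3.5 + c, 1.8 * wide, 2.8 * wide) + \
            _gauss(1.5 + r, side + 0.6 * c, 1.5, 1.0, tilt)
        bcg = _gauss(1.5 + r, 4.2 + c, 1.5 * wide, 2.3 * wide) + \
            _gauss(1.5 + r, side + 0.6 * c, 1.3, 0.9, 0.8 * tilt)
    elif posture in ("right_lateral", "left_lateral"):
        counter = float(rng.uniform(0.45, 0.95))  # moment-balance mass
        ridge_w = float(rng.lognormal(0.0, 0.25))
        resp = _gauss(1.5 + r, 0.8 + c, 1.6 * wide, 0.75 * ridge_w) + \
            _gauss(1.5 + r, 6.3 + 0.6 * c, 2.0, 2.7 * wide, counter)
        bcg = _gauss(1.5 + r, 1.0 + c, 1.4 * wide, 0.70 * ridge_w) + \
            _gauss(1.5 + r, 6.2 + 0.6 * c, 1.9, 2.5 * wide, 0.97 * counter)
        if posture == "left_lateral":
            resp, bcg = resp[:, ::-1], bcg[:, ::-1]
    else:
        raise ValueError(f"unknown posture {posture!r}")

    def perturb(w):
        return _norm(w * rng.lognormal(0.0, weight_sd, size=w.shape))

    return SpatialTemplate(posture, perturb(resp), perturb(bcg))


def jitter_template(template: SpatialTemplate, rng: np.random.Generator,
                    weight_sd: float = 0.35) -> SpatialTemplate:
    """Lognormal per-channel weight jitter of an existing template
    (within-night contact fluctuation)."""
    def perturb(w):
        return _norm(w * rng.lognormal(0.0, weight_sd, size=w.shape))

    return SpatialTemplate(template.posture,
                           perturb(template.resp_weights),
                           perturb(template.bcg_weights))


# ---------------------------------------------------------------------------
# posture schedules

def make_posture_schedule(total_minutes: int, rng_seed: int) -> PostureSchedule:
    """Random full-night posture schedule.

    Postures follow a no-immediate-repeat Markov chain with jump weights
    equal to the target time mix; supine bouts are drawn longer than
    lateral bouts (mean duration proportional to 1/(1 - pi_posture)), which
    makes the expected time-in-posture equal the target 49.8/33.6/16.7%
    split.  Full nights carry 15-25 posture changes.
    """
    if total_minutes < 60:
        raise ValueError("schedules shorter than 60 minutes are not supported")
    rng = np.random.default_rng(rng_seed)
    if total_minutes >= 270:
        n_seg = int(rng.integers(16, 27))
    else:
        n_seg = max(1, int(round(total_minutes / 20.0)) + int(rng.integers(-1, 2)))

    pis = np.array([POSTURE_MIX[p] for p in POSTURES])
    states = [int(rng.choice(3, p=pis))]
    while len(states) < n_seg:
        p = pis.copy()
        p[states[-1]] = 0.0
        states.append(int(rng.choice(3, p=p / p.sum())))

    mean_dur = np.array([1.0 / (1.0 - pis[s]) for s in states])
    raw = rng.gamma(4.0, mean_dur / 4.0)
    dur = np.maximum(1, np.round(raw / raw.sum() * total_minutes).astype(int))
    # fix rounding so durations sum exactly to total_minutes
    diff = total_minutes - int(dur.sum())
    i = int(np.argmax(dur))
    dur[i] = max(1, dur[i] + diff)
    segments = [(POSTURES[s], int(d)) for s, d in zip(states, dur)]
    return PostureSchedule(segments)


# ---------------------------------------------------------------------------
# waveform synthesis

def _anchored_cycle_phase(freq: float, duration: float, jitter_sd: float,
                          rng: np.random.Generator, fs: float = FS):
    """Phase(t)/2pi and a per-sample cycle index for a quasi-periodic source.

    Cycle boundary i is placed at (i + eta_i)/freq with eta mean-reverting
    (independent per boundary), so cycle durations fluctuate without the
    phase drifting away from the nominal grid -- jitter stays "per cycle"
    while minute-scale coherence survives, matching the narrowband spectra
    and high sinusoid-fit R^2 seen on the real mat.
    """
    n_cycles = int(np.ceil(duration * freq)) + 2
    # duration relative SD of (1 + eta_{i+1} - eta_i) is sqrt(2)*sd(eta)
    eta = rng.normal(0.0, jitter_sd / np.sqrt(2.0), size=n_cycles + 1)
    eta[0] = 0.0
    bounds = (np.arange(n_cycles + 1) + eta) / freq
    bounds = np.maximum.accumulate(bounds)           # keep strictly ordered
    t = np.arange(int(round(duration * fs))) / fs
    cycle = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, n_cycles - 1)
    left = bounds[cycle]
    width = bounds[cycle + 1] - left
    phase = cycle + (t - left) / width               # in cycles
    return phase, cycle


def synth_minute(profile: SubjectProfile, template: SpatialTemplate,
                 movement: bool, rng_seed: int,
                 duration_s: float = 60.0) -> MinuteSample:
    """Generate one labelled minute of 32-channel mat voltage."""
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration_s * FS))

    # respiration: jittered sinusoid
    ph_r, cyc_r = _anchored_cycle_phase(profile.fres, duration_s,
                                        profile.freq_jitter_sd, rng)
    amp_r = 1.0 + rng.normal(0.0, profile.amp_jitter_sd, size=cyc_r.max() + 1)
    u_res = profile.resp_amp * amp_r[cyc_r] * np.sin(2 * np.pi * ph_r)

    # BCG: AM carrier, five IJKL waves per heartbeat cycle
    ph_h, cyc_h = _anchored_cycle_phase(profile.fhea, duration_s,
                                        profile.freq_jitter_sd, rng)
    amp_h = 1.0 + rng.normal(0.0, profile.amp_jitter_sd, size=cyc_h.max() + 1)
    envelope = 1.0 + profile.mbcg * np.cos(2 * np.pi * ph_h)
    u_bcg = profile.bcg_amp * amp_h[cyc_h] * envelope * np.cos(2 * np.pi * 5.0 * ph_h)

    wr = template.resp_weights.ravel()[:, None]
    wb = template.bcg_weights.ravel()[:, None]
    wn = 0.5 * (wr + wb)
    clean = wr * u_res[None, :] + wb * u_bcg[None, :]
    noise = profile.noise_sd * wn * rng.standard_normal((N_CHANNELS, n))
    volts = clean + noise

    flags = np.zeros(N_CHANNELS, dtype=bool)
    if movement:
        k = int(rng.integers(7, N_CHANNELS + 1))
        channels = rng.choice(N_CHANNELS, size=k, replace=False)
        flags[channels] = True
        n_bursts = int(rng.integers(1, 5))
        starts = rng.uniform(0, duration_s - 10.0, size=n_bursts)
        lengths = rng.uniform(2.0, 10.0, size=n_bursts)
        clean_range = np.abs(clean).max(axis=1)      # per-channel clip scale
        for s0, dur in zip(starts, lengths):
            i0, i1 = int(s0 * FS), min(n, int((s0 + dur) * FS))
            m = i1 - i0
            for c in channels:
                step = clean_range[c] * 0.25
                walk = np.cumsum(rng.standard_normal(m)) * step
                clip = 3.0 * clean_range[c]
                volts[c, i0:i1] += np.clip(walk, -clip, clip)
                volts[c, i0:i1] = np.clip(volts[c, i0:i1], -clip, clip)
    return MinuteSample(volts, template.posture, bool(movement), flags)


# ---------------------------------------------------------------------------
# cohorts and datasets

def sample_profile(subject_id: str, rng: np.random.Generator,
                   movement_rate: float = 0.11) -> SubjectProfile:
    """Draw a subject from the cohort population."""
    return SubjectProfile(
        subject_id=subject_id,
        fres=float(np.clip(rng.normal(0.25, 0.025), 0.15, 0.40)),
        fhea=float(np.clip(rng.normal(1.2, 0.10), 0.9, 1.8)),
        resp_amp=float(rng.lognormal(0.0, 0.20)),
        bcg_amp=float(0.26 * rng.lognormal(0.0, 0.20)),
        mbcg=float(np.clip(rng.normal(0.4, 0.05), 0.15, 0.8)),
        movement_rate=float(np.clip(rng.normal(movement_rate, 0.02), 0.02, 0.30)),
    )


def _modulated(profile: SubjectProfile, posture: str) -> SubjectProfile:
    m = POSTURE_MODULATION[posture]
    return SubjectProfile(
        subject_id=profile.subject_id,
        fres=float(np.clip(profile.fres * m["fres"], 0.1, 0.8)),
        fhea=float(np.clip(profile.fhea * m["fhea"], 0.8, 3.0)),
        resp_amp=profile.resp_amp * m["resp_amp"],
        bcg_amp=profile.bcg_amp * m["bcg_amp"],
        mbcg=profile.mbcg,
        freq_jitter_sd=profile.freq_jitter_sd,
        amp_jitter_sd=profile.amp_jitter_sd,
        noise_sd=profile.noise_sd,
        movement_rate=profile.movement_rate,
    )


def plan_cohort(n_subjects: int, minutes_per_subject: int, master_seed: int,
                movement_rate: float = 0.11):
    """Deterministic per-minute plan (no waveforms).

    Returns ``(manifest, profiles, templates)`` where ``manifest`` is a
    DataFrame with one row per minute (subject_id, minute_index, posture,
    movement, seed) and ``templates`` maps (subject, posture) to the
    subject's jittered coupling template.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if minutes_per_subject < 60:
        raise ValueError("need at least 60 minutes per subject")
    root = np.random.SeedSequence(master_seed)
    rows = []
    profiles: dict[str, SubjectProfile] = {}
    templates: dict[tuple[str, str], SpatialTemplate] = {}
    for si, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        sid = f"s{si:02d}"
        profiles[sid] = sample_profile(sid, rng, movement_rate)
        for posture in POSTURES:
            templates[(sid, posture)] = subject_template(posture, rng)
        schedule = make_posture_schedule(minutes_per_subject,
                                         int(rng.integers(2**31)))
        labels = schedule.minute_labels()
        moving = rng.random(minutes_per_subject) < profiles[sid].movement_rate
        seeds = rng.integers(2**31, size=minutes_per_subject)
        for mi in range(minutes_per_subject):
            rows.append(dict(subject_id=sid, minute_index=mi, posture=labels[mi],
                             movement=int(moving[mi]), seed=int(seeds[mi])))
    manifest = pd.DataFrame(rows)
    return manifest, profiles, templates


def generate_minute(row, profiles, templates, minute_scale_sd: float = 0.05,
                    minute_weight_sd: float = 0.15,
                    fres_drift_sd: float = 0.06,
                    fhea_drift_sd: float = 0.04) -> MinuteSample:
    """Materialise the waveforms for one manifest row.

    On top of the subject's posture template, each minute carries a small
    overall gain fluctuation, per-channel coupling jitter (the body
    shifts slightly within a posture bout), and minute-scale drift of the
    breathing and heart rates -- nocturnal rates are not a fixed personal
    constant but wander a few percent with sleep depth.
    """
    profile = _modulated(profiles[row["subject_id"]], row["posture"])
    rng = np.random.default_rng(int(row["seed"]))
    scale = float(rng.lognormal(0.0, minute_scale_sd))
    profile.resp_amp *= scale
    profile.bcg_amp *= scale
    profile.fres = float(np.clip(profile.fres * rng.lognormal(0.0, fres_drift_sd),
                                 0.1, 0.8))
    profile.fhea = float(np.clip(profile.fhea * rng.lognormal(0.0, fhea_drift_sd),
                                 0.8, 3.0))
    template = jitter_template(templates[(row["subject_id"], row["posture"])],
                               rng, weight_sd=minute_weight_sd)
    return synth_minute(profile, template, bool(row["movement"]),
                        int(rng.integers(2**31)))


def synth_dataset(n_subjects: int, minutes_per_subject: int, master_seed: int,
                  out_dir: str | Path, movement_rate: float = 0.11,
                  waveforms: bool = True) -> pd.DataFrame:
    """Write a dataset directory: ``manifest.csv`` plus per-subject ``.npz``
    waveform containers (voltages float32, movement flags, postures).

    With ``waveforms=False`` only the manifest (and profile metadata) is
    written -- enough for cohort-statistics checks without the ~5 MB/minute
    waveform cost.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, profiles, templates = plan_cohort(
        n_subjects, minutes_per_subject, master_seed, movement_rate)
    files = []
    for sid, grp in manifest.groupby("subject_id", sort=True):
        fname = f"{sid}.npz"
        files.extend([fname] * len(grp))
        if waveforms:
            mins = [generate_minute(r, profiles, templates)
                    for _, r in grp.iterrows()]
            np.savez(out_dir / fname,
                     voltages=np.stack([m.voltages for m in mins]).astype(np.float32),
                     movement=np.array([m.movement for m in mins]),
                     per_channel_movement=np.stack([m.per_channel_movement
                                                    for m in mins]),
                     posture=np.array([m.posture for m in mins]))
    manifest = manifest.assign(file=files)
    cols = ["subject_id", "minute_index", "posture", "movement", "file", "seed"]
    manifest = manifest[cols]
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    meta = {sid: asdict(p) for sid, p in profiles.items()}
    (out_dir / "profiles.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return manifest


def dataset_fingerprint(out_dir: str | Path) -> str:
    """SHA-256 of the manifest text (determinism checks)."""
    return hashlib.sha256((Path(out_dir) / "manifest.csv").read_bytes()).hexdigest()
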