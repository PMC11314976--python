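"""End-to-end orchestration: simulate -> decompose -> screen -> features
-> train/evaluate, with file-based, resumable intermediates.

Every stage writes under one output directory and skips work whose
output file already exists, so a run is idempotent and a deleted
intermediate is regenerated selectively.  All randomness derives from
the single seed in :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthdata as sd
from .artifact import ArtifactDetector, sample_features
from .decompose import BandpassDecomposer, DecomposedSample, decompose_minute
from .evaluation import run_ablation, run_cv
from .s3cnn import pack_features
from .spatial_features import extract_spatial, RejectedFitError
from .temporal_features import extract_temporal, UnusableMinuteError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "sleepmat_run"
    n_subjects: int = 12
    minutes_per_subject: int = 120
    seed: int = 0
    movement_rate: float = 0.11
    artifact_threshold: int = 7
    folds: int = 10
    rounds: int = 3
    epochs: int = 30
    branches: str = "combined"
    use_true_flags: bool = False      # bypass the artifact MLP if True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# matrix and manifest I/O

def write_matrix(path, arr) -> None:
    """Delimited text (.txt/.csv, full precision) or binary (.npy)."""
    path = Path(path)
    arr = np.asarray(arr)
    if path.suffix == ".npy":
        np.save(path, arr)
    elif path.suffix in (".txt", ".csv"):
        np.savetxt(path, arr, fmt="%.18e",
                   delimiter="," if path.suffix == ".csv" else " ")
    else:
        raise ValueError(f"unsupported matrix format {path.suffix!r}")


def read_matrix(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    if path.suffix in (".txt", ".csv"):
        return np.atleast_2d(np.loadtxt(
            path, delimiter="," if path.suffix == ".csv" else None))
    raise ValueError(f"unsupported matrix format {path.suffix!r}")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path, validate_files: bool = False) -> pd.DataFrame:
    path = Path(path)
    try:
        manifest = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed manifest {path}: {err}") from err
    required = {"subject_id", "minute_index", "posture", "movement"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    if validate_files and "file" in manifest.columns:
        for i, row in manifest.iterrows():
            if not (path.parent / row["file"]).exists():
                raise ValueError(
                    f"manifest row {i} ({row['subject_id']} minute "
                    f"{row['minute_index']}): missing file {row['file']}")
    return manifest


# ---------------------------------------------------------------------------
# in-memory feature assembly (no intermediate files); used by the
# evaluation harness and the acceptance benchmark

def minute_features(dec: DecomposedSample) -> np.ndarray | None:
    """Packed 1564-feature vector of one clean minute, or None if the
    minute yields no usable fit/peaks."""
    try:
        maps = extract_spatial(dec)
        temporal = extract_temporal(dec)
    except (RejectedFitError, UnusableMinuteError) as err:
        log.warning("minute unusable: %s", err)
        return None
    return pack_features(temporal.M1, temporal.M2,
                         maps.upsampled_resp, maps.upsampled_bcg)


def dataset_features(n_subjects: int, minutes_per_subject: int, seed: int,
                     movement_rate: float = 0.11):
    """Simulate a cohort and extract features of the uninterfered minutes.

    Returns ``(X, y, groups)``; contaminated minutes are excluded by the
    generator's ground-truth movement flags.
    """
    manifest, profiles, templates = sd.plan_cohort(
        n_subjects, minutes_per_subject, seed, movement_rate)
    decomposer = BandpassDecomposer()
    rows_X, rows_y, rows_g = [], [], []
    clean = manifest[manifest["movement"] == 0]
    for _, row in clean.iterrows():
        minute = sd.generate_minute(row, profiles, templates)
        dec = decomposer.transform([minute])[0]
        x = minute_features(dec)
        if x is None:
            continue
        rows_X.append(x)
        rows_y.append(row["posture"])
        rows_g.append(row["subject_id"])
    return np.stack(rows_X), np.array(rows_y), np.array(rows_g)


# ---------------------------------------------------------------------------
# file-based stages

def simulate_stage(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    manifest_path = out / "manifest.csv"
    if manifest_path.exists():
        log.info("simulate: %s exists, skipping", manifest_path)
        return manifest_path
    sd.synth_dataset(cfg.n_subjects, cfg.minutes_per_subject, cfg.seed, out,
                     movement_rate=cfg.movement_rate)
    return manifest_path


def _load_subject(out: Path, sid: str):
    return np.load(out / f"{sid}.npz", allow_pickle=False)


def decompose_stage(cfg: RunConfig) -> Path:
    """Per-minute component files under components/ (float32 .npz)."""
    out = Path(cfg.out_dir)
    comp_dir = out / "components"
    comp_dir.mkdir(exist_ok=True)
    manifest = read_manifest(out / "manifest.csv")
    decomposer = BandpassDecomposer()
    for sid, grp in manifest.groupby("subject_id"):
        data = None
        for _, row in grp.iterrows():
            mi = int(row["minute_index"])
            target = comp_dir / f"{sid}_m{mi:04d}.npz"
            if target.exists():
                continue
            if data is None:
                data = _load_subject(out, sid)
            dec = decompose_minute(data["voltages"][mi].astype(float))
            np.savez(target,
                     resp=dec.resp.astype(np.float32),
                     bcg=dec.bcg.astype(np.float32),
                     dev=dec.dev.astype(np.float32),
                     composite_energy=dec.composite_energy,
                     resp_energy=dec.resp_energy,
                     bcg_energy=dec.bcg_energy,
                     dev_energy=dec.dev_energy)
    return comp_dir


def _load_component(comp_dir: Path, sid: str, mi: int) -> DecomposedSample:
    z = np.load(comp_dir / f"{sid}_m{mi:04d}.npz")
    return DecomposedSample(z["resp"].astype(float), z["bcg"].astype(float),
                            z["dev"].astype(float), z["composite_energy"],
                            z["resp_energy"], z["bcg_energy"], z["dev_energy"])


def artifact_stage(cfg: RunConfig) -> Path:
    """Train the channel MLP on generator ground truth and write
    flags.csv: the manifest plus predicted per-minute movement."""
    out = Path(cfg.out_dir)
    flags_path = out / "flags.csv"
    if flags_path.exists():
        log.info("detect-artifacts: %s exists, skipping", flags_path)
        return flags_path
    comp_dir = out / "components"
    manifest = read_manifest(out / "manifest.csv")
    feats, labels, keys = [], [], []
    for sid, grp in manifest.groupby("subject_id"):
        data = _load_subject(out, sid)
        for _, row in grp.iterrows():
            mi = int(row["minute_index"])
            dec = _load_component(comp_dir, sid, mi)
            f = sample_features(dec)
            feats.append(f)
            labels.append(data["per_channel_movement"][mi])
            keys.append((sid, mi))
    X = np.concatenate(feats)
    y = np.concatenate(labels)
    detector = ArtifactDetector(threshold=cfg.artifact_threshold,
                                random_state=cfg.seed).fit(X, y)
    predicted = detector.predict_minutes(feats)
    manifest = manifest.assign(predicted_movement=predicted.astype(int))
    write_manifest(manifest, flags_path)
    return flags_path


def features_stage(cfg: RunConfig) -> Path:
    """Per-minute packed feature files for predicted-clean minutes."""
    out = Path(cfg.out_dir)
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    comp_dir = out / "components"
    flag_col = "movement" if cfg.use_true_flags else "predicted_movement"
    manifest = read_manifest(out / "flags.csv")
    for _, row in manifest[manifest[flag_col] == 0].iterrows():
        sid, mi = row["subject_id"], int(row["minute_index"])
        target = feat_dir / f"{sid}_m{mi:04d}.npz"
        if target.exists():
            continue
        dec = _load_component(comp_dir, sid, mi)
        x = minute_features(dec)
        if x is None:
            continue
        np.savez(target, x=x.astype(np.float32), posture=row["posture"])
    return feat_dir


def load_feature_table(cfg: RunConfig):
    out = Path(cfg.out_dir)
    feat_dir = out / "features"
    Xs, ys, gs = [], [], []
    for f in sorted(feat_dir.glob("*.npz")):
        z = np.load(f)
        Xs.append(z["x"].astype(float))
        ys.append(str(z["posture"]))
        gs.append(f.name.split("_m")[0])
    return np.stack(Xs), np.array(ys), np.array(gs)


def evaluate_stage(cfg: RunConfig, ablate: bool = False):
    out = Path(cfg.out_dir)
    X, y, groups = load_feature_table(cfg)
    kw = dict(epochs=cfg.epochs)
    if ablate:
        reports = run_ablation(X, y, groups, k=cfg.folds, rounds=cfg.rounds,
                               seed=cfg.seed, estimator_kwargs=kw)
    else:
        kw["branches"] = cfg.branches
        reports = {cfg.branches: run_cv(X, y, groups, k=cfg.folds,
                                        rounds=cfg.rounds, seed=cfg.seed,
                                        estimator_kwargs=kw)}
    payload = {"config_hash": cfg.config_hash, "n_samples": int(len(y))}
    for name, rep in reports.items():
        payload[name] = {
            "summary": rep.summary(),
            "round_confusions": [c.tolist() for c in rep.round_confusions],
            "classes": [str(c) for c in rep.classes],
        }
    (out / "report.json").write_text(json.dumps(payload, indent=1))
    return reports


def run_pipeline(cfg: RunConfig, ablate: bool = False):
    """All stages in order; each is resumable from its files."""
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(Path(cfg.out_dir) / "config.yaml")
    for stage in (simulate_stage, decompose_stage, artifact_stage,
                  features_stage):
        try:
            stage(cfg)
        except Exception as err:
            raise RuntimeError(f"stage {stage.__name__} failed: {err}") from err
    return evaluate_stage(cfg, ablate=ablate)
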