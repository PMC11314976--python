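"""Four-branch spatiotemporal CNN for three-class sleep-posture detection.

Two shallow 1-D convolutional branches read the temporal feature
matrices (respiration 2 x 90, heartbeat 2 x 180; each row pair is
amplitude and inter-event interval), and two shallow 2-D branches read
the upsampled cardiorespiratory activity maps (fed with the long axis
first, 32 x 16, so the final (4, 2) valid convolution collapses the grid
to a single position).  Every branch ends in a 32-vector; the four
vectors are stacked into a 32 x 4 feature matrix, flattened, and passed
through fully connected layers of width 64 and 96 into a 3-way softmax.

Training: Adam (lr 1e-3), batch 48, at most 100 epochs, L2 weight decay
5e-4, a small L1 penalty on the dense head, dropout 0.5 after each head
layer.  All randomness is driven by one seed, so two fits with the same
data and seed produce identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

CLASSES = ("supine", "right_lateral", "left_lateral")
BRANCH_DIM = 32
M1_SHAPE = (2, 90)
M2_SHAPE = (2, 180)
MAP_INPUT_SHAPE = (32, 16)          # long (upsampled-column) axis first
_SIZES = (180, 360, 512, 512)       # flattened M1, M2, resp map, bcg map


@dataclass
class S3CNNConfig:
    """Layer and optimisation hyper-parameters (defaults per the design)."""

    conv1d_1: tuple = ((16, 11, 1), (24, 11, 2), (32, 11, 2))
    conv1d_2_pre: tuple = ((16, 11, 2), (24, 11, 2))
    conv1d_2_pool: tuple = (3, 1)               # pool size, stride
    conv1d_2_post: tuple = ((32, 11, 1),)
    head_widths: tuple = (64, 96)
    n_classes: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 48
    max_epochs: int = 100
    weight_decay: float = 5e-4
    l1: float = 1e-5
    dropout: float = 0.5


def _conv1d_branch(specs, rng, pool_after=None, post=None):
    layers = []
    c_in = 2
    for c_out, k, s in specs:
        layers += [nn.Conv1D(c_in, c_out, k, s, "same", rng=rng), nn.ReLU()]
        c_in = c_out
    if pool_after is not None:
        layers.append(nn.MaxPool1D(*pool_after))
    for c_out, k, s in (post or ()):
        layers += [nn.Conv1D(c_in, c_out, k, s, "same", rng=rng), nn.ReLU()]
        c_in = c_out
    layers.append(nn.GlobalAvgPool1D())
    return nn.Sequential(layers)


def _conv2d_branch_1(rng):
    return nn.Sequential([
        nn.Conv2D(1, 6, (3, 3), (2, 2), "same", rng=rng), nn.ReLU(),
        nn.Conv2D(6, 16, (3, 3), (2, 2), "same", rng=rng), nn.ReLU(),
        nn.MaxPool2D((2, 2)),
        nn.Conv2D(16, 32, (4, 2), (1, 1), "valid", rng=rng), nn.ReLU(),
        nn.GlobalMaxPool2D(),
    ])


def _conv2d_branch_2(rng):
    return nn.Sequential([
        nn.Conv2D(1, 12, (3, 3), (2, 2), "same", rng=rng), nn.ReLU(),
        nn.MaxPool2D((2, 2)),
        nn.Conv2D(12, 24, (3, 3), (1, 1), "same", rng=rng), nn.ReLU(),
        nn.MaxPool2D((2, 2)),
        nn.Conv2D(24, 32, (4, 2), (1, 1), "valid", rng=rng), nn.ReLU(),
        nn.GlobalMaxPool2D(),
    ])


class S3CNN:
    """The assembled network: selectable branches, stacked head."""

    def __init__(self, config: S3CNNConfig | None = None,
                 branches: str = "combined", seed: int = 0):
        self.config = cfg = config or S3CNNConfig()
        if branches not in ("combined", "temporal", "spatial"):
            raise ValueError("branches must be combined/temporal/spatial")
        self.branches = branches
        rng = np.random.default_rng(seed)
        self.temporal_branches = []
        self.spatial_branches = []
        if branches in ("combined", "temporal"):
            self.temporal_branches = [
                _conv1d_branch(cfg.conv1d_1, rng),
                _conv1d_branch(cfg.conv1d_2_pre, rng,
                               pool_after=cfg.conv1d_2_pool,
                               post=cfg.conv1d_2_post),
            ]
        if branches in ("combined", "spatial"):
            self.spatial_branches = [_conv2d_branch_1(rng), _conv2d_branch_2(rng)]
        n_branches = len(self.temporal_branches) + len(self.spatial_branches)
        head = []
        width = BRANCH_DIM * n_branches
        for w in cfg.head_widths:
            head += [nn.Dense(width, w, rng=rng, l1=cfg.l1), nn.ReLU(),
                     nn.Dropout(cfg.dropout, rng)]
            width = w
        head.append(nn.Dense(width, cfg.n_classes, rng=rng, l1=cfg.l1))
        self.head = nn.Sequential(head)
        self._validate_shapes()

    def _validate_shapes(self):
        inputs = self._dummy_inputs(2)
        feats = self.branch_features(inputs)
        for name, f in feats.items():
            if f.shape[1] != BRANCH_DIM:
                raise ValueError(f"branch {name} yields {f.shape[1]}-vectors, "
                                 f"expected {BRANCH_DIM}")

    def _dummy_inputs(self, n):
        return dict(M1=np.zeros((n,) + M1_SHAPE), M2=np.zeros((n,) + M2_SHAPE),
                    N1=np.zeros((n, 1) + MAP_INPUT_SHAPE),
                    N2=np.zeros((n, 1) + MAP_INPUT_SHAPE))

    def branch_features(self, inputs, training=False):
        feats = {}
        if self.temporal_branches:
            feats["F1"] = self.temporal_branches[0].forward(inputs["M1"], training)
            feats["F2"] = self.temporal_branches[1].forward(inputs["M2"], training)
        if self.spatial_branches:
            feats["E1"] = self.spatial_branches[0].forward(inputs["N1"], training)
            feats["E2"] = self.spatial_branches[1].forward(inputs["N2"], training)
        return feats

    def stacked_features(self, inputs, training=False):
        """(batch, 32, n_branches) stack of the branch outputs."""
        feats = self.branch_features(inputs, training)
        return np.stack(list(feats.values()), axis=-1)

    def forward(self, inputs, training=False):
        stacked = self.stacked_features(inputs, training)
        self._n_branches = stacked.shape[-1]
        flat = stacked.reshape(stacked.shape[0], -1)
        return self.head.forward(flat, training=training)

    def backward(self, dlogits):
        dflat = self.head.backward(dlogits)
        d = dflat.reshape(dflat.shape[0], BRANCH_DIM, self._n_branches)
        order = []
        if self.temporal_branches:
            order += self.temporal_branches
        if self.spatial_branches:
            order += self.spatial_branches
        for i, branch in enumerate(order):
            branch.backward(d[..., i])

    def predict_proba(self, inputs):
        return nn.softmax(self.forward(inputs, training=False))

    def all_layers(self):
        layers = []
        for br in self.temporal_branches + self.spatial_branches:
            layers += list(br.iter_layers())
        layers += list(self.head.iter_layers())
        return layers

    def parameter_count(self):
        return nn.parameter_count(self.all_layers())

    def get_weights(self):
        return [p.copy() for layer in self.all_layers() for p in layer.params]


def build_s3cnn(config: S3CNNConfig | None = None, branches: str = "combined",
                seed: int = 0) -> S3CNN:
    return S3CNN(config, branches, seed)


# ---------------------------------------------------------------------------
# feature packing: one flat vector per sample so the estimator composes
# with sklearn model selection

def pack_features(m1: np.ndarray, m2: np.ndarray,
                  resp_map: np.ndarray, bcg_map: np.ndarray) -> np.ndarray:
    """Flatten one sample's features into a 1564-vector.

    Maps arrive as 16 x 32 images and are transposed to 32 x 16 (long
    axis first) and max-normalised per map.
    """
    parts = [np.asarray(m1, dtype=float).reshape(-1),
             np.asarray(m2, dtype=float).reshape(-1)]
    for m in (resp_map, bcg_map):
        m = np.asarray(m, dtype=float)
        if m.shape == (16, 32):
            m = m.T
        if m.shape != MAP_INPUT_SHAPE:
            raise ValueError("maps must be 16x32 or 32x16")
        mx = m.max()
        parts.append((m / mx if mx > 0 else m).reshape(-1))
    return np.concatenate(parts)


def unpack_features(X: np.ndarray):
    """Inverse of :func:`pack_features` for a batch."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != sum(_SIZES):
        raise ValueError(f"expected {sum(_SIZES)} columns, got {X.shape[1]}")
    ofs = np.cumsum((0,) + _SIZES)
    n = X.shape[0]
    return dict(
        M1=X[:, ofs[0]:ofs[1]].reshape(n, *M1_SHAPE),
        M2=X[:, ofs[1]:ofs[2]].reshape(n, *M2_SHAPE),
        N1=X[:, ofs[2]:ofs[3]].reshape(n, 1, *MAP_INPUT_SHAPE),
        N2=X[:, ofs[3]:ofs[4]].reshape(n, 1, *MAP_INPUT_SHAPE),
    )


class PostureCNN(ClassifierMixin, BaseEstimator):
    """sklearn-compatible wrapper around :class:`S3CNN`.

    ``X`` is an (n, 1564) matrix of packed features (see
    :func:`pack_features`); ``y`` holds posture labels.  Temporal rows are
    z-scored per row type with statistics learned from the training set
    (fitted attribute ``scaler_``); maps are already in [0, 1].
    """

    def __init__(self, branches: str = "combined", learning_rate: float = 1e-3,
                 batch_size: int = 48, epochs: int = 100,
                 weight_decay: float = 5e-4, l1: float = 1e-5,
                 dropout: float = 0.5, random_state: int = 0,
                 verbose: bool = False):
        self.branches = branches
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.l1 = l1
        self.dropout = dropout
        self.random_state = random_state
        self.verbose = verbose

    # -- internals --------------------------------------------------------
    def _config(self):
        return S3CNNConfig(learning_rate=self.learning_rate,
                           batch_size=self.batch_size,
                           max_epochs=self.epochs,
                           weight_decay=self.weight_decay,
                           l1=self.l1, dropout=self.dropout)

    def _normalise(self, inputs, fit=False):
        out = {k: v.copy() for k, v in inputs.items()}
        if fit:
            self.scaler_ = {}
            for key in ("M1", "M2"):
                mu = out[key].mean(axis=(0, 2), keepdims=True)
                sd = out[key].std(axis=(0, 2), keepdims=True)
                sd[sd == 0] = 1.0
                self.scaler_[key] = (mu, sd)
        for key in ("M1", "M2"):
            mu, sd = self.scaler_[key]
            out[key] = (out[key] - mu) / sd
        return out

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training set must contain at least two classes")
        n_epochs = min(self.epochs, 100)    # hard cap
        inputs = self._normalise(unpack_features(X), fit=True)
        onehot = np.eye(len(self.classes_))[y_idx]

        self.model_ = S3CNN(self._config(), self.branches,
                            seed=self.random_state)
        opt = nn.Adam(self.model_.all_layers(), lr=self.learning_rate,
                      weight_decay=self.weight_decay)
        rng = np.random.default_rng(self.random_state + 1)
        n = X.shape[0]
        self.history_ = {"loss": [], "accuracy": []}
        for epoch in range(n_epochs):
            order = rng.permutation(n)
            ep_loss, ep_hits = 0.0, 0
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                batch = {k: v[sel] for k, v in inputs.items()}
                logits = self.model_.forward(batch, training=True)
                loss, dlogits = nn.softmax_xent(logits, onehot[sel])
                self.model_.backward(dlogits)
                opt.step()
                ep_loss += loss * len(sel)
                ep_hits += int((logits.argmax(1) == y_idx[sel]).sum())
            self.history_["loss"].append(ep_loss / n)
            self.history_["accuracy"].append(ep_hits / n)
            if self.verbose:
                print(f"epoch {epoch + 1}: loss={ep_loss / n:.4f} "
                      f"acc={ep_hits / n:.3f}")
        self.n_features_in_ = X.shape[1]
        return self

    def _forward(self, X):
        inputs = self._normalise(unpack_features(np.asarray(X, dtype=float)))
        # evaluate in batches to bound memory
        probs = []
        n = next(iter(inputs.values())).shape[0]
        for start in range(0, n, 256):
            batch = {k: v[start:start + 256] for k, v in inputs.items()}
            probs.append(self.model_.predict_proba(batch))
        return np.vstack(probs)

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self._forward(X)

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]


def save_model(clf: PostureCNN, path) -> None:
    """Serialise a fitted classifier: hyper-parameters, class order,
    normalisation statistics, and all layer weights."""
    import json
    from pathlib import Path
    check_is_fitted(clf, "model_")
    params = clf.get_params()
    blob = {"params": params,
            "classes": [str(c) for c in clf.classes_],
            "config_hash": __import__("hashlib").sha256(
                json.dumps(params, sort_keys=True).encode()).hexdigest()[:12]}
    arrays = {f"w{i}": w for i, w in enumerate(clf.model_.get_weights())}
    for key in ("M1", "M2"):
        mu, sd = clf.scaler_[key]
        arrays[f"mu_{key}"], arrays[f"sd_{key}"] = mu, sd
    np.savez(Path(path), meta=np.frombuffer(
        json.dumps(blob).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> PostureCNN:
    """Rebuild a classifier saved by :func:`save_model`."""
    import json
    z = np.load(path)
    blob = json.loads(bytes(z["meta"]))
    clf = PostureCNN(**blob["params"])
    clf.classes_ = np.array(blob["classes"])
    clf.scaler_ = {key: (z[f"mu_{key}"], z[f"sd_{key}"])
                   for key in ("M1", "M2")}
    clf.model_ = S3CNN(clf._config(), clf.branches, seed=clf.random_state)
    layers = clf.model_.all_layers()
    i = 0
    for layer in layers:
        for p in layer.params:
            p[...] = z[f"w{i}"]
            i += 1
    clf.n_features_in_ = sum(_SIZES)
    return clf


def train_model(model: S3CNN, train_set, config: S3CNNConfig, seed: int = 0):
    """Functional trainer for an assembled :class:`S3CNN`.

    ``train_set`` is ``(inputs, labels)`` with ``inputs`` the branch dict
    and integer ``labels``.  Returns the model and its history.
    """
    inputs, labels = train_set
    labels = np.asarray(labels)
    if len(np.unique(labels)) < config.n_classes:
        raise ValueError("all classes must be present in the training set")
    onehot = np.eye(config.n_classes)[labels]
    opt = nn.Adam(model.all_layers(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    rng = np.random.default_rng(seed)
    n = labels.size
    history = {"loss": [], "accuracy": []}
    for _ in range(min(config.max_epochs, 100)):
        order = rng.permutation(n)
        ep_loss, hits = 0.0, 0
        for s in range(0, n, config.batch_size):
            sel = order[s:s + config.batch_size]
            logits = model.forward({k: v[sel] for k, v in inputs.items()},
                                   training=True)
            loss, dl = nn.softmax_xent(logits, onehot[sel])
            model.backward(dl)
            opt.step()
            ep_loss += loss * len(sel)
            hits += int((logits.argmax(1) == labels[sel]).sum())
        history["loss"].append(ep_loss / n)
        history["accuracy"].append(hits / n)
    return model, history


def predict(model: S3CNN, inputs):
    """Class probabilities and argmax labels for a branch-input dict."""
    probs = model.predict_proba(inputs)
    return probs, probs.argmax(axis=1)
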