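"""Hybrid 3D-1D convolutional patch classifier.

Architecture (per patch, p x p spatial by B' spectral bands):

    input (p, p, B', 1)
      -> Conv3D x 2, ReLU            (joint spatial-spectral features)
      -> collapse spatial dims
      -> Conv1D x 2 along spectra, ReLU
      -> flatten -> dropout -> dense softmax over 3 tissue classes

Training minimizes class-weighted cross-entropy with early stopping on
the validation F1-score of the cancer class — the clinically critical,
heavily under-represented class.  The implementation is pure numpy
(im2col convolutions with explicit backprop); at patch scale the tensors
are tiny and a BLAS matmul per layer is fast enough for CPU training.

Class indices are 0 = esophagus, 1 = stomach, 2 = cancer (mask label - 1).
Ties in the softmax argmax break toward the lower class index.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .hsi_io import AnnotationMask, HyperCube

__all__ = [
    "ModelConfig",
    "PatchDataset",
    "TrainedModel",
    "extract_patches",
    "subsample_patches",
    "class_weights",
    "build_model",
    "train",
    "predict_proba",
    "predict_map",
    "random_search",
]

N_CLASSES = 3
CANCER_CLASS = 2


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow the published training setup (3x3 patches, batch 128,
    learning rate 1e-4, Adadelta); filter counts and kernels are modest so
    the model trains on a single CPU core in minutes at desk scale.
    """

    patch_size: int = 3
    conv3d_filters: tuple = (8, 16)
    conv3d_spectral_kernel: int = 7
    conv1d_filters: tuple = (32, 64)
    conv1d_kernel: int = 5
    dropout_rate: float = 0.5
    n_classes: int = N_CLASSES
    batch_size: int = 128
    learning_rate: float = 0.0001
    optimizer_name: str = "adadelta"
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 1 or self.patch_size % 2 == 0:
            raise ConfigurationError("patch_size must be odd >= 1")
        if not 0.0 < self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must be in (0, 1]")
        if any(c < 1 for c in (*self.conv3d_filters, *self.conv1d_filters)):
            raise ConfigurationError("filter counts must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("batch_size and max_epochs must be >= 1")
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")


@dataclass
class PatchDataset:
    """Labeled patches with patient provenance.

    patches : (N, p, p, B') float array
    labels  : (N,) int class indices in {0, 1, 2}
    patient_ids : (N,) strings
    """

    patches: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.patient_ids = np.asarray(self.patient_ids)
        if not (len(self.patches) == len(self.labels) == len(self.patient_ids)):
            raise ValueError("patches/labels/patient_ids length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @staticmethod
    def concatenate(datasets: list) -> "PatchDataset":
        return PatchDataset(
            np.concatenate([d.patches for d in datasets]),
            np.concatenate([d.labels for d in datasets]),
            np.concatenate([d.patient_ids for d in datasets]),
        )


def extract_patches(cube: HyperCube, mask: AnnotationMask, patch_size: int = 3) -> PatchDataset:
    """One patch per labeled pixel whose full neighborhood fits in the image.

    The label is the center pixel's class; no padding is used, so pixels
    within (p-1)/2 of the border yield no patch.  Row order is the
    row-major scan of eligible centers (deterministic).
    """
    if patch_size % 2 == 0 or patch_size < 1:
        raise ValueError("patch_size must be odd >= 1")
    mask.check_aligned(cube)
    r = patch_size // 2
    h, w, _ = cube.shape
    interior = np.zeros((h, w), dtype=bool)
    interior[r:h - r, r:w - r] = True
    eligible = (mask.labels > 0) & interior
    ii, jj = np.nonzero(eligible)
    if ii.size == 0:
        raise ValueError("no labeled pixel has a full patch neighborhood")
    win = np.lib.stride_tricks.sliding_window_view(cube.reflectance, (patch_size, patch_size),
                                                   axis=(0, 1))
    # win: (h-p+1, w-p+1, B, p, p) -> select centers, reorder to (N, p, p, B)
    patches = win[ii - r, jj - r].transpose(0, 2, 3, 1)
    labels = mask.labels[ii, jj].astype(np.int64) - 1
    pids = np.full(ii.size, cube.patient_id, dtype=object)
    return PatchDataset(np.ascontiguousarray(patches), labels, pids)


def subsample_patches(ds: PatchDataset, n_max: int, seed: int = 0,
                      stratified: bool = True) -> PatchDataset:
    """Seeded random subsample, by default stratified by class so rare
    classes keep proportionally more examples than a uniform draw."""
    if len(ds) <= n_max:
        return ds
    rng = np.random.default_rng(seed)
    if stratified:
        keep: list = []
        classes = np.unique(ds.labels)
        per = n_max // classes.size
        for c in classes:
            idx = np.nonzero(ds.labels == c)[0]
            take = min(idx.size, per)
            keep.append(rng.choice(idx, size=take, replace=False))
        keep = np.concatenate(keep)
        # top up with uniform remainder
        if keep.size < n_max:
            rest = np.setdiff1d(np.arange(len(ds)), keep, assume_unique=False)
            extra = rng.choice(rest, size=min(rest.size, n_max - keep.size), replace=False)
            keep = np.concatenate([keep, extra])
        keep.sort()
    else:
        keep = np.sort(rng.choice(len(ds), size=n_max, replace=False))
    return PatchDataset(ds.patches[keep], ds.labels[keep], ds.patient_ids[keep])


def class_weights(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Balanced class weights w_c = N / (K * n_c).

    The weighted mean of w over the label distribution is exactly 1, so
    weighting rescales per-class gradients without changing the overall
    loss scale.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=n_classes).astype(np.float64)
    if np.any(counts == 0):
        missing = np.nonzero(counts == 0)[0].tolist()
        raise ValueError(f"classes absent from the labels: {missing}")
    return counts.sum() / (n_classes * counts)


# ---------------------------------------------------------------------------
# Layers (im2col 3-D convolutions; 1-D convs reuse the same machinery with
# unit spatial kernels)

class _Conv3D:
    def __init__(self, kernel: tuple, cin: int, cout: int, rng: np.random.Generator):
        kh, kw, kb = kernel
        fan_in = kh * kw * kb * cin
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kh, kw, kb, cin, cout))
        self.b = np.zeros(cout)
        self.kernel = kernel

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (N, H, W, B, C)
        kh, kw, kb = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw, kb), axis=(1, 2, 3))
        # win: (N, H', W', B', C, kh, kw, kb)
        self._win = win
        self._xshape = x.shape
        n, ho, wo, bo = win.shape[:4]
        # cols are (kh,kw,kb,cin)-ordered, matching the weight layout
        cols = win.transpose(0, 1, 2, 3, 5, 6, 7, 4).reshape(n * ho * wo * bo, -1)
        wmat = self.W.reshape(-1, self.W.shape[-1])
        out = cols @ wmat + self.b
        return out.reshape(n, ho, wo, bo, -1)

    def backward(self, dy: np.ndarray):
        kh, kw, kb = self.kernel
        n, ho, wo, bo, cout = dy.shape
        cols = self._win.transpose(0, 1, 2, 3, 5, 6, 7, 4).reshape(n * ho * wo * bo, -1)
        dflat = dy.reshape(-1, cout)
        self.dW = (cols.T @ dflat).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        dx = np.zeros(self._xshape)
        wr = self.W.reshape(kh, kw, kb, -1, cout)
        for i in range(kh):
            for j in range(kw):
                for k in range(kb):
                    contrib = dflat @ wr[i, j, k].T  # (n*ho*wo*bo, cin)
                    dx[:, i:i + ho, j:j + wo, k:k + bo, :] += contrib.reshape(n, ho, wo, bo, -1)
        self._win = None
        return dx

    @property
    def grads(self):
        return [self.dW, self.db]


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _CollapseSpatial:
    """(N, h, w, B, C) -> (N, 1, 1, B, h*w*C): feeds spatial features into
    the 1-D spectral convolutions as channels."""

    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        n, h, w, b, c = x.shape
        return x.transpose(0, 3, 1, 2, 4).reshape(n, 1, 1, b, h * w * c)

    def backward(self, dy):
        n, h, w, b, c = self._shape
        return dy.reshape(n, b, h, w, c).transpose(0, 2, 3, 1, 4)


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Dropout:
    params: list = []
    grads: list = []

    def __init__(self, rate: float):
        self.rate = rate
        self.training = False
        self.rng = np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.rate >= 1.0 or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), (nin, nout))
        self.b = np.zeros(nout)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx

    @property
    def grads(self):
        return [self.dW, self.db]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Optimizers

class _Adadelta:
    """Adadelta with a learning-rate multiplier on the self-scaled step."""

    def __init__(self, params, lr=1.0, rho=0.95, eps=1e-6):
        self.params, self.lr, self.rho, self.eps = params, lr, rho, eps
        self.eg = [np.zeros_like(p) for p in params]
        self.ed = [np.zeros_like(p) for p in params]

    def step(self, grads):
        for p, g, eg, ed in zip(self.params, grads, self.eg, self.ed):
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            delta = -np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * g
            ed *= self.rho
            ed += (1 - self.rho) * delta * delta
            p += self.lr * delta


class _Adam:
    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.params, self.lr, self.b1, self.b2, self.eps = params, lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, params, lr=1e-2):
        self.params, self.lr = params, lr

    def step(self, grads):
        for p, g in zip(self.params, grads):
            p -= self.lr * g


_OPTIMIZERS = {"adadelta": _Adadelta, "adam": _Adam, "sgd": _SGD}


# ---------------------------------------------------------------------------
# Model

@dataclass
class TrainedModel:
    """Network parameters plus the configuration and training history."""

    config: ModelConfig
    n_bands: int
    layers: list = field(default_factory=list, repr=False)
    history: list = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for layer in self.layers for p in layer.params))

    def _all_params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits for a batch of patches (N, p, p, B')."""
        h = x[..., None]  # channel axis
        for layer in self.layers:
            if isinstance(layer, _Dropout):
                layer.training = training
            h = layer.forward(h)
        return h

    def predict_proba(self, patches: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        out = []
        for i in range(0, len(patches), batch_size):
            out.append(_softmax(self.forward(patches[i:i + batch_size], training=False)))
        return np.concatenate(out) if out else np.zeros((0, self.config.n_classes))

    def snapshot(self) -> list:
        return [p.copy() for p in self._all_params()]

    def restore(self, snap: list) -> None:
        for p, s in zip(self._all_params(), snap):
            p[...] = s

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        blobs = {f"param_{i}": p for i, p in enumerate(self._all_params())}
        cfg = asdict(self.config)
        cfg["conv3d_filters"] = list(cfg["conv3d_filters"])
        cfg["conv1d_filters"] = list(cfg["conv1d_filters"])
        np.savez(path, __meta__=json.dumps({"config": cfg, "n_bands": self.n_bands,
                                            "history": self.history}),
                 **blobs)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as arch:
            meta = json.loads(str(arch["__meta__"]))
            cfg = meta["config"]
            cfg["conv3d_filters"] = tuple(cfg["conv3d_filters"])
            cfg["conv1d_filters"] = tuple(cfg["conv1d_filters"])
            model = build_model(ModelConfig(**cfg), meta["n_bands"])
            model.history = meta["history"]
            for i, p in enumerate(model._all_params()):
                p[...] = arch[f"param_{i}"]
        return model


def build_model(config: ModelConfig, n_bands: int) -> TrainedModel:
    """Assemble the (untrained) hybrid 3D-1D CNN for ``n_bands`` input bands.

    Initialization is He-normal, fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.patch_size
    kb = config.conv3d_spectral_kernel
    layers: list = []

    h = w = p
    b = n_bands
    cin = 1
    for cout in config.conv3d_filters:
        kh = min(3, h)
        kw = min(3, w)
        if b < kb:
            raise ConfigurationError(
                f"spectral kernel {kb} exceeds remaining band extent {b}")
        layers += [_Conv3D((kh, kw, kb), cin, cout, rng), _ReLU()]
        h, w, b, cin = h - kh + 1, w - kw + 1, b - kb + 1, cout

    layers.append(_CollapseSpatial())
    cin = cin * h * w
    h = w = 1
    for cout in config.conv1d_filters:
        if b < config.conv1d_kernel:
            raise ConfigurationError(
                f"1-D kernel {config.conv1d_kernel} exceeds remaining band extent {b}")
        layers += [_Conv3D((1, 1, config.conv1d_kernel), cin, cout, rng), _ReLU()]
        b, cin = b - config.conv1d_kernel + 1, cout

    layers.append(_Flatten())
    drop = _Dropout(config.dropout_rate if config.dropout_rate < 1.0 else 0.0)
    drop.rng = np.random.default_rng(config.seed + 1)
    layers.append(drop)
    layers.append(_Dense(b * cin, config.n_classes, rng))
    return TrainedModel(config=config, n_bands=n_bands, layers=layers)


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def train(model: TrainedModel, train_set: PatchDataset, val_set: PatchDataset,
          config: ModelConfig | None = None, verbose: bool = False) -> TrainedModel:
    """Fit with class-weighted cross-entropy and cancer-F1 early stopping.

    After each epoch the validation cancer F1 is computed; when it fails
    to improve for ``early_stop_patience`` consecutive epochs, training
    stops and the best-epoch parameters are restored.
    """
    config = config or model.config
    train_pids = set(np.unique(train_set.patient_ids).tolist())
    val_pids = set(np.unique(val_set.patient_ids).tolist())
    if train_pids & val_pids:
        raise ValueError(f"train/validation patients overlap: {sorted(train_pids & val_pids)}")
    if not np.any(val_set.labels == CANCER_CLASS):
        raise ValueError("validation set lacks the cancer class needed for early stopping")

    weights = class_weights(train_set.labels, config.n_classes)
    opt_cls = _OPTIMIZERS.get(config.optimizer_name.lower())
    if opt_cls is None:
        raise ConfigurationError(f"unknown optimizer {config.optimizer_name!r}")
    opt = opt_cls(model._all_params(), lr=config.learning_rate)

    rng = np.random.default_rng(config.seed + 2)
    n = len(train_set)
    best_f1 = -np.inf
    best_snap = model.snapshot()
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            x, y = train_set.patches[idx], train_set.labels[idx]
            logits = model.forward(x, training=True)
            probs = _softmax(logits)
            sw = weights[y]
            eps = 1e-12
            total_loss += float(-(sw * np.log(probs[np.arange(len(y)), y] + eps)).sum())
            dlogits = probs.copy()
            dlogits[np.arange(len(y)), y] -= 1.0
            dlogits *= sw[:, None] / len(y)
            grad = dlogits
            grads: list = []
            for layer in reversed(model.layers):
                grad = layer.backward(grad)
                grads = list(layer.grads) + grads
            opt.step(grads)

        val_probs = model.predict_proba(val_set.patches, config.batch_size * 8)
        val_pred = val_probs.argmax(axis=1)
        f1 = _binary_f1(val_set.labels == CANCER_CLASS, val_pred == CANCER_CLASS)
        model.history.append({"epoch": epoch, "train_loss": total_loss / n,
                              "val_cancer_f1": f1})
        if verbose:
            print(f"epoch {epoch}: loss {total_loss / n:.4f}  val cancer F1 {f1:.3f}")
        if f1 > best_f1:
            best_f1 = f1
            best_snap = model.snapshot()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.early_stop_patience:
                break
    model.restore(best_snap)
    return model


def predict_proba(model: TrainedModel, patches: np.ndarray) -> np.ndarray:
    return model.predict_proba(patches)


def predict_map(model: TrainedModel, cube: HyperCube,
                batch_size: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise prediction over a preprocessed cube.

    Returns ``(label_map, prob_maps)``: label_map is H x W with mask-enum
    labels {1, 2, 3} on the predictable interior and 0 (no prediction) on
    the border; prob_maps is H x W x 3 with NaN where no prediction exists.
    """
    if cube.n_bands != model.n_bands:
        raise ValueError(f"cube has {cube.n_bands} bands, model expects {model.n_bands}")
    p = model.config.patch_size
    r = p // 2
    h, w, _ = cube.shape
    win = np.lib.stride_tricks.sliding_window_view(cube.reflectance, (p, p), axis=(0, 1))
    ho, wo = win.shape[:2]
    patches = win.reshape(ho * wo, cube.n_bands, p, p).transpose(0, 2, 3, 1)
    probs = model.predict_proba(np.ascontiguousarray(patches), batch_size)
    label_map = np.zeros((h, w), dtype=np.uint8)
    prob_maps = np.full((h, w, model.config.n_classes), np.nan)
    inner = probs.argmax(axis=1).reshape(ho, wo).astype(np.uint8) + 1
    label_map[r:r + ho, r:r + wo] = inner
    prob_maps[r:r + ho, r:r + wo] = probs.reshape(ho, wo, -1)
    return label_map, prob_maps


# ---------------------------------------------------------------------------
# Hyperparameter search

def random_search(train_set: PatchDataset, val_set: PatchDataset, n_bands: int,
                  n_trials: int = 5, seed: int = 0,
                  space: dict | None = None) -> tuple[ModelConfig, list]:
    """Seeded random search over a small hyperparameter space.

    Stands in for full Bayesian optimization: draws ``n_trials`` configs,
    trains each briefly, and returns the config with the best validation
    cancer F1 together with the trial log.
    """
    space = space or {
        "patch_size": [3, 5],
        "learning_rate": [3e-4, 1e-3, 3e-3],
        "dropout_rate": [0.3, 0.5],
        "conv1d_kernel": [3, 5],
    }
    rng = np.random.default_rng(seed)
    trials = []
    best = (None, -np.inf)
    for t in range(n_trials):
        draw = {k: v[rng.integers(len(v))] for k, v in space.items()}
        cfg = ModelConfig(optimizer_name="adam", max_epochs=3, early_stop_patience=1,
                          seed=seed + t, **draw)
        model = build_model(cfg, n_bands)
        model = train(model, train_set, val_set, cfg)
        f1 = max(h["val_cancer_f1"] for h in model.history)
        trials.append({**draw, "val_cancer_f1": f1})
        if f1 > best[1]:
            best = (cfg, f1)
    return best[0], trials
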