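"""The two stream models: EmgCNN (scalogram images) and EmgLSTM (feature sequences).

Both are trained with Adam (first-moment decay 0.9), cross-entropy loss,
classic L2 regularization and a step learning-rate schedule that
multiplies the rate by ``lr_decay`` every ``lr_step`` epochs.  Both emit
softmax score vectors — nonnegative, summing to one — which are the
currency of score-level late fusion.

The default CNN backbone is a small residual network (a stem
convolution, two residual blocks and a global average pool) that trains
on a CPU at desk scale; a deeper ResNet-style stack of residual stages
is available via ``backbone="deep_residual"``.  No pretrained weights
are bundled.  The sequence model is a sequence-to-one bidirectional
LSTM: the forward pass's final hidden state and the backward pass's
final hidden state are concatenated and mapped linearly to class logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from emgfusion import _nn
from emgfusion.scalogram import ScalogramImage
from emgfusion.time_features import FeatureSequence

__all__ = [
    "CnnConfig",
    "LstmConfig",
    "CnnModel",
    "LstmModel",
    "train_cnn",
    "predict_cnn_scores",
    "train_lstm",
    "predict_lstm_scores",
    "as_score_vectors",
]


def as_score_vectors(scores: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Validate an (n, C) array of score vectors (nonnegative, rows sum to 1)."""
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2:
        raise ValueError("scores must be 2-D (n, C)")
    if np.any(s < 0):
        raise ValueError("scores must be nonnegative")
    if not np.allclose(s.sum(axis=1), 1.0, atol=atol):
        raise ValueError("score vectors must sum to 1")
    return s


@dataclass
class CnnConfig:
    """Training configuration for the image stream.

    Defaults follow the reference training recipe: Adam with mini-batch
    20, initial learning rate 1e-4, momentum (beta1) 0.9, learning-rate
    decay 0.2 every 5 epochs, L2 penalty 1e-4, 10 epochs, no
    augmentation.  ``width`` is the stem channel count of the small
    residual backbone.
    """

    n_classes: int
    input_shape: tuple[int, int, int] = (224, 224, 3)
    backbone: str = "small_residual"
    batch_size: int = 20
    initial_lr: float = 1e-4
    lr_decay: float = 0.2
    lr_step: int = 5
    l2_penalty: float = 1e-4
    max_epochs: int = 10
    beta1: float = 0.9
    width: int = 8
    head: str = "flatten"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.backbone not in ("small_residual", "deep_residual"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.head not in ("flatten", "gap"):
            raise ValueError(f"unknown head {self.head!r}; use 'flatten' or 'gap'")
        h, w, p = self.input_shape
        if p % 3 != 0:
            raise ValueError("input planes must be a multiple of 3")
        if h % 16 or w % 16:
            raise ValueError("input height/width must be divisible by 16")


@dataclass
class LstmConfig:
    """Training configuration for the sequence stream.

    Defaults follow the reference recipe: input size 5 (one slot per
    time-domain feature), 500 hidden units per direction, bidirectional,
    Adam with mini-batch 500, initial learning rate 0.01, decay 0.2
    every 5 epochs, L2 penalty 1e-4, 300 epochs.  ``standardize``
    z-scores each feature row with statistics fit on the training set
    (the feature rows live on very different scales — volts vs counts).
    """

    n_classes: int
    input_size: int = 5
    hidden_units: int = 500
    bidirectional: bool = True
    batch_size: int = 500
    initial_lr: float = 0.01
    lr_decay: float = 0.2
    lr_step: int = 5
    l2_penalty: float = 1e-4
    max_epochs: int = 300
    beta1: float = 0.9
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_size < 1:
            raise ValueError("input_size must be >= 1")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must be in (0, 1]")


def _encode_labels(labels: Sequence, n_classes: int) -> tuple[np.ndarray, list]:
    classes = sorted(set(labels), key=str)
    if len(classes) != n_classes:
        raise ValueError(
            f"training set covers {len(classes)} classes but config declares {n_classes}; "
            "every class must be present"
        )
    index = {c: i for i, c in enumerate(classes)}
    return np.array([index[l] for l in labels]), classes


def _lr_at(epoch: int, initial: float, decay: float, step: int) -> float:
    return initial * decay ** (epoch // step)


def _to_image_array(images) -> np.ndarray:
    arrs = [im.pixels if isinstance(im, ScalogramImage) else np.asarray(im, float) for im in images]
    return np.stack(arrs)


# ---------------------------------------------------------------------------
# CNN


class CnnModel:
    """A residual CNN over HxWxP images, trained by :func:`train_cnn`.

    Architecture (small_residual, width w): conv3x3/2 -> pool2 ->
    resblock(w) -> pool2 -> resblock(w->2w, stride 2) -> head -> linear.
    The head either flattens the final feature map (default; keeps the
    time/frequency position of spectral energy, which is where subject
    identity lives in a scalogram) or global-average-pools it.  The
    deep_residual variant appends two further stride-2 residual stages
    (4w, 8w).  Inputs are standardized with per-pixel training-set
    statistics when ``config.standardize`` is set.
    """

    def __init__(self, config: CnnConfig, rng: np.random.Generator):
        self.config = config
        self.classes_: list = []
        self.history: pd.DataFrame | None = None
        h, w, planes = config.input_shape
        self.norm_mean = np.zeros(config.input_shape)
        self.norm_std = np.ones(config.input_shape)
        wd = config.width
        self.stages = [wd, 2 * wd] if config.backbone == "small_residual" else [wd, 2 * wd, 4 * wd, 8 * wd]
        p: dict[str, np.ndarray] = {}

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        p["stem_W"] = he((wd, planes, 3, 3), planes * 9)
        p["stem_b"] = np.zeros(wd)
        cin = wd
        hh, ww = h // 2 // 2, w // 2 // 2  # after stem + first pool
        for si, cout in enumerate(self.stages):
            stride = 1 if si == 0 else 2
            p[f"s{si}_W1"] = he((cout, cin, 3, 3), cin * 9)
            p[f"s{si}_b1"] = np.zeros(cout)
            p[f"s{si}_W2"] = he((cout, cout, 3, 3), cout * 9)
            p[f"s{si}_b2"] = np.zeros(cout)
            if stride != 1 or cin != cout:
                p[f"s{si}_Wp"] = he((cout, cin, 1, 1), cin)
                p[f"s{si}_bp"] = np.zeros(cout)
            cin = cout
            if stride == 2:
                hh, ww = (hh - 1) // 2 + 1, (ww - 1) // 2 + 1
            if si == 0:
                hh, ww = hh // 2, ww // 2  # pool after first stage
        feat_dim = cin if config.head == "gap" else cin * hh * ww
        p["fc_W"] = rng.normal(0.0, np.sqrt(1.0 / feat_dim), size=(feat_dim, config.n_classes))
        p["fc_b"] = np.zeros(config.n_classes)
        self.params = p

    def forward(self, x: np.ndarray):
        """x: (B, H, W, P) in [0,1] -> logits (B, C) plus backward cache."""
        caches: list = []
        if self.config.standardize:
            x = (x - self.norm_mean) / self.norm_std
        h = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
        h, c = _nn.conv2d_forward(h, self.params["stem_W"], self.params["stem_b"], stride=2, pad=1)
        caches.append(("stem", c))
        h, m = _nn.relu_forward(h)
        caches.append(("relu", m))
        h, shp = _nn.avgpool2_forward(h)
        caches.append(("pool", shp))
        for si in range(len(self.stages)):
            stride = 1 if si == 0 else 2
            skip = h
            out, c1 = _nn.conv2d_forward(
                h, self.params[f"s{si}_W1"], self.params[f"s{si}_b1"], stride=stride, pad=1
            )
            out, m1 = _nn.relu_forward(out)
            out, c2 = _nn.conv2d_forward(
                out, self.params[f"s{si}_W2"], self.params[f"s{si}_b2"], stride=1, pad=1
            )
            if f"s{si}_Wp" in self.params:
                skip, cp = _nn.conv2d_forward(
                    h, self.params[f"s{si}_Wp"], self.params[f"s{si}_bp"], stride=stride, pad=0
                )
            else:
                cp = None
            out = out + skip
            out, m2 = _nn.relu_forward(out)
            caches.append((f"res{si}", (c1, m1, c2, cp, m2)))
            h = out
            if si == 0:
                h, shp = _nn.avgpool2_forward(h)
                caches.append(("pool", shp))
        head_shape = h.shape
        feat = h.mean(axis=(2, 3)) if self.config.head == "gap" else h.reshape(h.shape[0], -1)
        caches.append(("head", head_shape))
        logits = feat @ self.params["fc_W"] + self.params["fc_b"]
        caches.append(("fc", feat))
        return logits, caches

    def backward(self, dlogits: np.ndarray, caches) -> dict:
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        it = list(caches)
        name, feat = it.pop()
        grads["fc_W"] = feat.T @ dlogits
        grads["fc_b"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["fc_W"].T
        name, head_shape = it.pop()
        B, C, H, W = head_shape
        if self.config.head == "gap":
            dh = np.ascontiguousarray(
                np.broadcast_to(dfeat[:, :, None, None], head_shape) / (H * W)
            )
        else:
            dh = dfeat.reshape(head_shape)
        si = len(self.stages) - 1
        while it:
            name, cache = it.pop()
            if name == "pool":
                dh = _nn.avgpool2_backward(dh, cache)
            elif name.startswith("res"):
                c1, m1, c2, cp, m2 = cache
                dout = _nn.relu_backward(dh, m2)
                dskip = dout
                d2, grads[f"s{si}_W2"], grads[f"s{si}_b2"] = _nn.conv2d_backward(dout, c2)
                d2 = _nn.relu_backward(d2, m1)
                d1, grads[f"s{si}_W1"], grads[f"s{si}_b1"] = _nn.conv2d_backward(d2, c1)
                if cp is not None:
                    dp, grads[f"s{si}_Wp"], grads[f"s{si}_bp"] = _nn.conv2d_backward(dskip, cp)
                    dh = d1 + dp
                else:
                    dh = d1 + dskip
                si -= 1
            elif name == "relu":
                dh = _nn.relu_backward(dh, cache)
            elif name == "stem":
                _, grads["stem_W"], grads["stem_b"] = _nn.conv2d_backward(dh, cache)
        return grads

    def predict_scores(self, images, batch_size: int = 32) -> np.ndarray:
        x = _to_image_array(images)
        if x.shape[1:] != tuple(self.config.input_shape):
            raise ValueError(
                f"image shape {x.shape[1:]} does not match model input {self.config.input_shape}"
            )
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits, _ = self.forward(x[i : i + batch_size])
            out.append(_nn.softmax(logits))
        return np.vstack(out)


def train_cnn(train_images, train_labels, config: CnnConfig, test_images=None, test_labels=None) -> CnnModel:
    """Train the image-stream CNN; returns the model with a per-epoch history.

    ``train_images`` is a sequence of :class:`ScalogramImage` (or raw
    HxWxP arrays); labels may be any hashable values covering exactly
    ``config.n_classes`` classes.
    """
    x = _to_image_array(train_images)
    if x.shape[1:] != tuple(config.input_shape):
        raise ValueError(f"images are {x.shape[1:]}, config expects {config.input_shape}")
    y, classes = _encode_labels(train_labels, config.n_classes)
    rng = np.random.default_rng(config.seed)
    model = CnnModel(config, rng)
    model.classes_ = classes
    if config.standardize:
        model.norm_mean = x.mean(axis=0)
        std = x.std(axis=0)
        model.norm_std = np.where(std > 1e-8, std, 1.0)
    opt = _nn.Adam(model.params, beta1=config.beta1)
    rows = []
    n = x.shape[0]
    for epoch in range(config.max_epochs):
        lr = _lr_at(epoch, config.initial_lr, config.lr_decay, config.lr_step)
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits, caches = model.forward(x[idx])
            loss, probs, dlogits = _nn.softmax_cross_entropy(logits, y[idx])
            grads = model.backward(dlogits, caches)
            opt.step(model.params, grads, lr, config.l2_penalty)
            losses.append(loss * idx.size)
            correct += int(np.sum(probs.argmax(axis=1) == y[idx]))
        row = {
            "epoch": epoch + 1,
            "lr": lr,
            "loss": float(np.sum(losses) / n),
            "train_acc": correct / n,
        }
        if test_images is not None:
            scores = model.predict_scores(test_images)
            pred = [classes[i] for i in scores.argmax(axis=1)]
            row["test_acc"] = float(np.mean([p == t for p, t in zip(pred, test_labels)]))
        rows.append(row)
    model.history = pd.DataFrame(rows)
    return model


def predict_cnn_scores(model: CnnModel, images) -> np.ndarray:
    """Softmax score vectors, one row per image, in input order."""
    return as_score_vectors(model.predict_scores(images))


# ---------------------------------------------------------------------------
# BiLSTM


class LstmModel:
    """Sequence-to-one (bidirectional) LSTM over 5-row feature sequences."""

    def __init__(self, config: LstmConfig, rng: np.random.Generator):
        self.config = config
        self.classes_: list = []
        self.history: pd.DataFrame | None = None
        self.norm_mean = np.zeros(config.input_size)
        self.norm_std = np.ones(config.input_size)
        D, H, C = config.input_size, config.hidden_units, config.n_classes
        p: dict[str, np.ndarray] = {}
        directions = ["f", "b"] if config.bidirectional else ["f"]
        for d in directions:
            p[f"Wx_{d}"] = rng.normal(0.0, np.sqrt(1.0 / D), size=(D, 4 * H))
            p[f"Wh_{d}"] = rng.normal(0.0, np.sqrt(1.0 / H), size=(H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            p[f"b_{d}"] = b
        feat_dim = H * len(directions)
        p["fc_W"] = rng.normal(0.0, np.sqrt(1.0 / feat_dim), size=(feat_dim, C))
        p["fc_b"] = np.zeros(C)
        self.params = p
        self.directions = directions

    def _normalize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.norm_mean[None, :, None]) / self.norm_std[None, :, None]

    def forward(self, x: np.ndarray):
        """x: (B, D, T) feature sequences -> logits (B, C) plus cache."""
        xt = np.ascontiguousarray(x.transpose(2, 0, 1))  # (T, B, D)
        hs, caches = [], {}
        for d in self.directions:
            inp = xt if d == "f" else xt[::-1]
            h, cache = _nn.lstm_forward(
                inp, self.params[f"Wx_{d}"], self.params[f"Wh_{d}"], self.params[f"b_{d}"]
            )
            hs.append(h)
            caches[d] = cache
        feat = np.concatenate(hs, axis=1)
        logits = feat @ self.params["fc_W"] + self.params["fc_b"]
        return logits, (caches, feat)

    def backward(self, dlogits: np.ndarray, cache) -> dict:
        caches, feat = cache
        grads = {}
        grads["fc_W"] = feat.T @ dlogits
        grads["fc_b"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["fc_W"].T
        H = self.config.hidden_units
        for di, d in enumerate(self.directions):
            dh = dfeat[:, di * H : (di + 1) * H]
            _, dWx, dWh, db = _nn.lstm_backward(dh, caches[d])
            grads[f"Wx_{d}"] = dWx
            grads[f"Wh_{d}"] = dWh
            grads[f"b_{d}"] = db
        return grads

    def predict_scores(self, sequences) -> np.ndarray:
        out = np.empty((len(sequences), self.config.n_classes))
        for idx_group, batch in _length_batches(sequences, range(len(sequences)), batch_size=512):
            logits, _ = self.forward(self._normalize(batch))
            out[idx_group] = _nn.softmax(logits)
        return out


def _seq_values(seq) -> np.ndarray:
    v = seq.values if isinstance(seq, FeatureSequence) else np.asarray(seq, dtype=float)
    if v.ndim != 2:
        raise ValueError("each sequence must be a 2-D (features x time) matrix")
    return v


def _length_batches(sequences, indices, batch_size: int, rng: np.random.Generator | None = None):
    """Yield (index-array, (B, D, T) batch) groups of equal-length sequences."""
    by_len: dict[int, list[int]] = {}
    for i in indices:
        by_len.setdefault(_seq_values(sequences[i]).shape[1], []).append(i)
    for T in sorted(by_len):
        idx = np.array(by_len[T])
        if rng is not None:
            idx = idx[rng.permutation(idx.size)]
        for i in range(0, idx.size, batch_size):
            sel = idx[i : i + batch_size]
            batch = np.stack([_seq_values(sequences[j]) for j in sel])
            yield sel, batch


def train_lstm(train_sequences, train_labels, config: LstmConfig, test_sequences=None, test_labels=None) -> LstmModel:
    """Train the sequence-stream BiLSTM; returns the model with history.

    Sequences are ``FeatureSequence`` objects or (D, T) arrays sharing
    D = ``config.input_size``; T may vary across the dataset (batches
    are grouped by length).
    """
    D = config.input_size
    for s in train_sequences:
        v = _seq_values(s)
        if v.shape[0] != D:
            raise ValueError(f"sequence has {v.shape[0]} feature rows, config expects {D}")
    y, classes = _encode_labels(train_labels, config.n_classes)
    rng = np.random.default_rng(config.seed)
    model = LstmModel(config, rng)
    model.classes_ = classes
    if config.standardize:
        flat = np.hstack([_seq_values(s) for s in train_sequences])
        model.norm_mean = flat.mean(axis=1)
        std = flat.std(axis=1)
        model.norm_std = np.where(std > 1e-12, std, 1.0)
    opt = _nn.Adam(model.params, beta1=config.beta1)
    rows = []
    n = len(train_sequences)
    for epoch in range(config.max_epochs):
        lr = _lr_at(epoch, config.initial_lr, config.lr_decay, config.lr_step)
        losses, correct = [], 0
        for sel, batch in _length_batches(train_sequences, rng.permutation(n), config.batch_size, rng):
            logits, cache = model.forward(model._normalize(batch))
            loss, probs, dlogits = _nn.softmax_cross_entropy(logits, y[sel])
            grads = model.backward(dlogits, cache)
            opt.step(model.params, grads, lr, config.l2_penalty)
            losses.append(loss * sel.size)
            correct += int(np.sum(probs.argmax(axis=1) == y[sel]))
        row = {
            "epoch": epoch + 1,
            "lr": lr,
            "loss": float(np.sum(losses) / n),
            "train_acc": correct / n,
        }
        if test_sequences is not None:
            scores = model.predict_scores(test_sequences)
            pred = [classes[i] for i in scores.argmax(axis=1)]
            row["test_acc"] = float(np.mean([p == t for p, t in zip(pred, test_labels)]))
        rows.append(row)
    model.history = pd.DataFrame(rows)
    return model


def predict_lstm_scores(model: LstmModel, sequences) -> np.ndarray:
    """Softmax score vectors, one row per sequence, in input order."""
    for s in sequences:
        if _seq_values(s).shape[0] != model.config.input_size:
            raise ValueError("sequence feature-row count does not match model input size")
    return as_score_vectors(model.predict_scores(sequences))


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: CnnModel | LstmModel, path) -> None:
    """Save weights + config + class labels to a single .npz checkpoint."""
    import dataclasses
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    kind = "cnn" if isinstance(model, CnnModel) else "lstm"
    meta = {
        "kind": kind,
        "config": dataclasses.asdict(model.config),
        "classes": list(map(str, model.classes_)),
    }
    extra = {"norm_mean": model.norm_mean, "norm_std": model.norm_std}
    np.savez(path, __meta__=json.dumps(meta), **model.params, **extra)


def load_model(path) -> "CnnModel | LstmModel":
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = meta["config"]
    if meta["kind"] == "cnn":
        cfg["input_shape"] = tuple(cfg["input_shape"])
        model: CnnModel | LstmModel = CnnModel(CnnConfig(**cfg), np.random.default_rng(0))
    else:
        model = LstmModel(LstmConfig(**cfg), np.random.default_rng(0))
    model.norm_mean = arrays.pop("norm_mean")
    model.norm_std = arrays.pop("norm_std")
    for k in model.params:
        model.params[k] = arrays[k]
    model.classes_ = meta["classes"]
    return model
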