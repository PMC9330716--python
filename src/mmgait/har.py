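"""Four-layer CNN mapping micro-Doppler spectrograms to gait-class probabilities.

Architecture: four blocks of [3x3 conv -> leaky ReLU -> 2x2 max pool ->
dropout 5%] with channel depths 32/64/128/256, flattened into a single dense
softmax layer with one node per gait class.  Training uses Adam on
cross-entropy with an 80/20 split and early stopping on validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .kinematics import GAIT_CLASSES
from .spectrogram import (MicroDopplerSpectrogram, log_compress,
                          resample_spectrogram)


@dataclass(frozen=True)
class ActivityClassifierSpec:
    conv_depths: tuple = (32, 64, 128, 256)
    kernel: int = 3
    leaky_slope: float = 0.01
    dropout_prob: float = 0.05
    n_classes: int = 5
    input_shape: tuple = (64, 64)


@dataclass(frozen=True)
class ActivityPrediction:
    """Class probabilities plus the argmax class label."""

    probabilities: np.ndarray
    predicted_class: str

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
            raise ValueError("probabilities must be a non-negative vector "
                             "summing to one")


def build_classifier(spec: ActivityClassifierSpec = ActivityClassifierSpec(),
                     seed: int = 0) -> nn.Sequential:
    """Assemble the classifier; raises if the input is too small to pool."""
    h, w = spec.input_shape
    n_pool = len(spec.conv_depths)
    if min(h, w) < 2 ** n_pool:
        raise ValueError(f"input {spec.input_shape} too small for "
                         f"{n_pool} pooling stages")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    for depth in spec.conv_depths:
        layers += [
            nn.Conv2D(in_ch, depth, spec.kernel, rng=rng),
            nn.LeakyReLU(spec.leaky_slope),
            nn.MaxPool2D(),
            nn.Dropout(spec.dropout_prob),
        ]
        in_ch = depth
    flat = (h // 2 ** n_pool) * (w // 2 ** n_pool) * spec.conv_depths[-1]
    layers += [nn.Flatten(), nn.Dense(flat, spec.n_classes, rng=rng)]
    return nn.Sequential(layers)


def _as_batch(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    return x[:, None, :, :]          # (n, 1, h, w)


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Label-preserving spectrogram augmentation.

    Walking toward vs away from the sensor mirrors the velocity axis, and a
    window may start anywhere in the gait cycle, so velocity/time flips and
    small circular shifts leave the class unchanged.
    """
    x = x.copy()
    n = len(x)
    flip_v = rng.random(n) < 0.5
    flip_t = rng.random(n) < 0.5
    x[flip_v] = x[flip_v, :, ::-1, :]
    x[flip_t] = x[flip_t, :, :, ::-1]
    for i in range(n):
        x[i] = np.roll(x[i], rng.integers(-6, 7), axis=2)     # time
        x[i] = np.roll(x[i], rng.integers(-2, 3), axis=1)     # velocity
    return x


def train_classifier(model: nn.Sequential, spectrograms: np.ndarray,
                     labels: np.ndarray, epochs: int = 30, seed: int = 0,
                     batch_size: int = 32, lr: float = 1e-3,
                     val_fraction: float = 0.2, patience: int = 5,
                     val_mask: np.ndarray | None = None,
                     augment: bool = True) -> dict:
    """Train on (n, 64, 64) spectrograms with integer class labels 0..k-1.

    ``val_mask`` pins specific samples to validation (e.g. held-out
    subjects); otherwise a random ``val_fraction`` split is used.  Early
    stopping restores the best-validation-loss weights.  Returns a history
    dict with per-epoch train/val loss and accuracy.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs at least two classes")
    x = _as_batch(spectrograms)
    rng = np.random.default_rng(seed)
    n = len(x)
    if val_mask is None:
        perm = rng.permutation(n)
        n_val = max(int(round(val_fraction * n)), 1) if val_fraction > 0 else 0
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
    else:
        val_mask = np.asarray(val_mask, bool)
        val_idx = np.flatnonzero(val_mask)
        tr_idx = np.flatnonzero(~val_mask)
    if len(tr_idx) == 0:
        raise ValueError("empty training split")
    xt, yt = x[tr_idx], labels[tr_idx]
    xv, yv = x[val_idx], labels[val_idx]

    opt = nn.Adam(model.params(), lr=lr)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_val, best_state, bad = np.inf, None, 0
    for epoch in range(epochs):
        order = rng.permutation(len(xt))
        losses, correct = [], 0
        for start in range(0, len(xt), batch_size):
            idx = order[start:start + batch_size]
            xb = _augment_batch(xt[idx], rng) if augment else xt[idx]
            logits = model.forward(xb, train=True, rng=rng)
            loss, grad = nn.softmax_cross_entropy(logits, yt[idx])
            model.backward(grad)
            opt.step()
            losses.append(loss)
            correct += int(np.sum(np.argmax(logits, axis=1) == yt[idx]))
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / len(xt))
        if len(xv):
            vl, va = _evaluate(model, xv, yv, batch_size)
        else:
            vl, va = history["train_loss"][-1], history["train_acc"][-1]
        history["val_loss"].append(vl)
        history["val_acc"].append(va)
        if vl < best_val - 1e-5:
            best_val, bad = vl, 0
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        else:
            bad += 1
            if bad >= patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return history


def _evaluate(model, x, y, batch_size=64):
    losses, correct = [], 0
    for start in range(0, len(x), batch_size):
        logits = model.forward(x[start:start + batch_size], train=False)
        loss, _ = nn.softmax_cross_entropy(logits, y[start:start + batch_size])
        losses.append(loss * len(logits))
        correct += int(np.sum(np.argmax(logits, axis=1)
                              == y[start:start + batch_size]))
    return float(np.sum(losses) / len(x)), correct / len(x)


def predict_probabilities(model: nn.Sequential, spectrograms,
                          batch_size: int = 64) -> np.ndarray:
    """(n, k) class probabilities, deterministic (dropout off)."""
    x = _as_batch(spectrograms)
    out = []
    for start in range(0, len(x), batch_size):
        out.append(nn.softmax(model.forward(x[start:start + batch_size],
                                            train=False)))
    return np.concatenate(out, axis=0)


def classify(model: nn.Sequential,
             spec: MicroDopplerSpectrogram | np.ndarray) -> ActivityPrediction:
    """Classify one spectrogram (resampled to the CNN input shape)."""
    if isinstance(spec, MicroDopplerSpectrogram):
        img = log_compress(resample_spectrogram(spec))
    else:
        img = np.asarray(spec, dtype=np.float32)
    probs = predict_probabilities(model, img[None])[0].astype(float)
    probs = probs / probs.sum()
    return ActivityPrediction(probabilities=probs,
                              predicted_class=GAIT_CLASSES[int(np.argmax(probs))])
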