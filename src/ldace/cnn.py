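"""Compact 1-D convolutional feature extractor, implemented in numpy.

The pair vectors are high-dimensional and locally structured (rows of
similarity matrices), so a small 1-D CNN — conv/ReLU/max-pool blocks
followed by a dense layer — is trained as a binary classifier with a
sigmoid head, and the activations of the last dense layer are exposed as
the low-dimensional features fed to the downstream ELM classifier.

Training uses manual backpropagation and Adam; everything is seeded so a
fixed configuration and dataset reproduce bit-identical features.  An
``identity`` mode bypasses the network entirely and hands the raw
similarity features to the ELM, which serves as an ablation baseline and
keeps the rest of the pipeline testable independently of the CNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class CNNConfig:
    """Architecture and optimization settings.

    ``conv_blocks`` is a list of ``(filters, kernel_width, pool_width)``
    triples applied in order; ``dense_units`` is the dimensionality of the
    extracted features.
    """

    conv_blocks: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(16, 8, 4), (32, 8, 4)]
    )
    dense_units: int = 64
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dense_units < 1:
            raise ValueError("dense_units must be >= 1")
        for f, k, p in self.conv_blocks:
            if f < 1 or k < 1 or p < 1:
                raise ValueError("filters, kernel and pool widths must be >= 1")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class _ConvBlock:
    """Valid 1-D convolution + ReLU + non-overlapping max pooling."""

    def __init__(self, c_in: int, filters: int, kernel: int, pool: int, rng):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, size=(filters, c_in, kernel))
        self.b = np.zeros(filters)
        self.pool = pool
        self.kernel = kernel

    def out_length(self, length: int) -> int:
        conv_len = length - self.kernel + 1
        if conv_len < 1:
            raise ValueError("kernel width exceeds sequence length")
        pooled = conv_len // self.pool
        if pooled < 1:
            raise ValueError("pool width exceeds convolved length")
        return pooled

    def forward(self, x: np.ndarray):
        # x: (batch, c_in, L)
        windows = sliding_window_view(x, self.kernel, axis=2)  # (B, Cin, L', k)
        conv = np.einsum("bilk,oik->bol", windows, self.W) + self.b[None, :, None]
        relu = np.maximum(conv, 0.0)
        pooled_len = relu.shape[2] // self.pool
        trimmed = relu[:, :, : pooled_len * self.pool]
        windowsed = trimmed.reshape(*trimmed.shape[:2], pooled_len, self.pool)
        out = windowsed.max(axis=3)
        cache = (x, windows, conv, windowsed, out)
        return out, cache

    def backward(self, d_out: np.ndarray, cache):
        x, windows, conv, windowsed, out = cache
        # unpool: route gradient to the max position of each window
        is_max = windowsed == out[..., None]
        # break ties by keeping only the first max in each window
        first = np.cumsum(is_max, axis=3) == 1
        is_max &= first
        d_trim = (is_max * d_out[..., None]).reshape(
            windowsed.shape[0], windowsed.shape[1], -1
        )
        d_relu = np.zeros_like(conv)
        d_relu[:, :, : d_trim.shape[2]] = d_trim
        d_conv = d_relu * (conv > 0)
        dW = np.einsum("bilk,bol->oik", windows, d_conv)
        db = d_conv.sum(axis=(0, 2))
        d_x = np.zeros_like(x, dtype=float)
        conv_len = d_conv.shape[2]
        for t in range(self.kernel):
            d_x[:, :, t : t + conv_len] += np.einsum(
                "bol,oi->bil", d_conv, self.W[:, :, t]
            )
        return d_x, dW, db


class _CNN:
    """Conv blocks -> flatten -> dense(ReLU) -> linear sigmoid head."""

    def __init__(self, input_length: int, config: CNNConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.blocks: list[_ConvBlock] = []
        c_in, length = 1, input_length
        for filters, kernel, pool in config.conv_blocks:
            blk = _ConvBlock(c_in, filters, kernel, pool, rng)
            length = blk.out_length(length)
            self.blocks.append(blk)
            c_in = filters
        flat = c_in * length
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, config.dense_units))
        self.b1 = np.zeros(config.dense_units)
        self.W2 = rng.normal(0.0, np.sqrt(1.0 / config.dense_units),
                             size=(config.dense_units, 1))
        self.b2 = np.zeros(1)
        self.input_length = input_length
        self._rng = rng

    def _params(self) -> list[np.ndarray]:
        ps = []
        for blk in self.blocks:
            ps += [blk.W, blk.b]
        ps += [self.W1, self.b1, self.W2, self.b2]
        return ps

    def forward(self, X: np.ndarray):
        h = X[:, None, :]
        caches = []
        for blk in self.blocks:
            h, cache = blk.forward(h)
            caches.append(cache)
        flat = h.reshape(h.shape[0], -1)
        dense_pre = flat @ self.W1 + self.b1
        features = np.maximum(dense_pre, 0.0)
        logits = features @ self.W2 + self.b2
        return logits.ravel(), features, (caches, h.shape, flat, dense_pre, features)

    def features(self, X: np.ndarray) -> np.ndarray:
        _, feats, _ = self.forward(X)
        return feats

    def loss_and_grads(self, xb: np.ndarray, yb: np.ndarray):
        """Mean binary cross-entropy and its gradients w.r.t. all parameters."""
        logits, _, cache = self.forward(xb)
        caches, h_shape, flat, dense_pre, features = cache
        p = _sigmoid(logits)
        eps = 1e-12
        loss = -float(
            np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
        )
        d_logits = (p - yb) / len(yb)
        dW2 = features.T @ d_logits[:, None]
        db2 = np.array([d_logits.sum()])
        d_feat = d_logits[:, None] @ self.W2.T
        d_dense = d_feat * (dense_pre > 0)
        dW1 = flat.T @ d_dense
        db1 = d_dense.sum(axis=0)
        d_flat = d_dense @ self.W1.T
        d_h = d_flat.reshape(h_shape)
        grads_blocks: list[np.ndarray] = []
        for blk, blk_cache in zip(reversed(self.blocks), reversed(caches)):
            d_h, dW, db = blk.backward(d_h, blk_cache)
            grads_blocks = [dW, db] + grads_blocks
        return loss, grads_blocks + [dW1, db1, dW2, db2]

    def train(self, X: np.ndarray, y: np.ndarray) -> None:
        cfg = self.config
        n = X.shape[0]
        opt = _Adam(self._params(), cfg.learning_rate)
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                _, grads = self.loss_and_grads(X[idx], y[idx])
                opt.step(grads)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _, _ = self.forward(X)
        return _sigmoid(logits)


@dataclass
class FeatureExtractor:
    """Trained transform from pair vectors to low-dimensional features.

    ``mode="identity"`` passes vectors through unchanged; ``mode="cnn"``
    returns the last dense layer's ReLU activations of a trained network.
    """

    mode: str
    input_length: int
    output_length: int
    _net: _CNN | None = None

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        if vectors.shape[1] != self.input_length:
            raise ValueError(
                f"expected vectors of length {self.input_length}, "
                f"got {vectors.shape[1]}"
            )
        if self.mode == "identity":
            return vectors.copy()
        assert self._net is not None
        return self._net.features(vectors)


def train_extractor(data, config: CNNConfig | None = None, mode: str = "cnn"
                    ) -> FeatureExtractor:
    """Train the CNN on a labeled pair set and return its feature transform.

    The network is fit as a binary classifier (sigmoid head, cross-entropy)
    on the provided data only; the extractor then maps any vector of the
    same length to the penultimate-layer activations.  Requires at least
    two samples of each class.
    """
    X = np.asarray(data.vectors, dtype=float)
    y = np.asarray(data.labels, dtype=float)
    length = X.shape[1]
    if mode == "identity":
        return FeatureExtractor("identity", length, length)
    if config is None:
        config = CNNConfig()
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError("need at least 2 samples of each class to train")
    net = _CNN(length, config)
    net.train(X, y)
    return FeatureExtractor("cnn", length, config.dense_units, _net=net)


def extract(extractor: FeatureExtractor, vectors: np.ndarray) -> np.ndarray:
    """Apply a trained extractor to a matrix of pair vectors."""
    return extractor.transform(vectors)
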