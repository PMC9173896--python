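"""CNN feature extraction from segmented lesion images.

The default backend is a compact convolutional network written on plain
numpy: three conv blocks (8/16/32 filters of size 3, stride 1, ReLU,
2x2 max-pool) followed by global average pooling and a logistic
classification head.  It is trained with mini-batch stochastic gradient
descent on binary cross-entropy over the user's own training split, and
the penultimate activation — the global-average-pooled vector — is the
feature representation handed to the downstream classifier.

Input images are masked (background zeroed, so only the segmented
lesion is visible) and resized to a fixed square input, which makes the
feature length independent of the original image size.

An ``nasnet_pretrained`` backend name is reserved for an adapter around
an ImageNet-pretrained NASNet behind the same interface; it requires an
optional deep-learning runtime and downloaded weights, and is not used
by the default pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExtractorConfig",
    "SgdConfig",
    "FeatureVector",
    "CompactCnnExtractor",
    "conv2d_valid",
    "max_pool",
    "sgd_step",
    "train_extractor",
    "extract_features",
]


@dataclass(frozen=True)
class SgdConfig:
    learning_rate: float = 0.005
    epochs: int = 100
    batch_size: int = 8
    momentum: float = 0.9

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")


@dataclass(frozen=True)
class ExtractorConfig:
    backend: str = "compact_cnn"
    conv_blocks: tuple[tuple[int, int, int], ...] = (
        (8, 3, 1),
        (16, 3, 1),
        (32, 3, 1),
    )
    pool_size: int = 2
    feature_dim: int = 32
    input_size: int = 64
    sgd: SgdConfig = field(default_factory=SgdConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("compact_cnn", "nasnet_pretrained"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        for n_filters, ksize, stride in self.conv_blocks:
            if stride < 1:
                raise ValueError("strides must be >= 1")
            if ksize < 1 or ksize % 2 == 0:
                raise ValueError("kernel sizes must be odd and >= 1")
            if n_filters < 1:
                raise ValueError("filter counts must be >= 1")
        if self.conv_blocks[-1][0] != self.feature_dim:
            raise ValueError(
                "feature_dim must equal the last block's filter count "
                "(features are the global average pool of the last map)"
            )


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    source_id: str = ""


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def conv2d_valid(
    input_2d: np.ndarray, kernel: np.ndarray, stride: int = 1
) -> np.ndarray:
    """Valid-region 2-D cross-correlation: sliding-window dot products.

    Output[i, j] = sum of ``input[i*s : i*s+kh, j*s : j*s+kw] * kernel``.
    """
    x = np.asarray(input_2d, dtype=float)
    k = np.asarray(kernel, dtype=float)
    if k.shape[0] > x.shape[0] or k.shape[1] > x.shape[1]:
        raise ValueError("kernel larger than input")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    windows = np.lib.stride_tricks.sliding_window_view(x, k.shape)
    windows = windows[::stride, ::stride]
    return np.einsum("ijkl,kl->ij", windows, k)


def max_pool(input_2d: np.ndarray, pool_size: int) -> np.ndarray:
    """Non-overlapping max pooling; ragged edges are padded with -inf."""
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    x = np.asarray(input_2d, dtype=float)
    h, w = x.shape
    ph = (-h) % pool_size
    pw = (-w) % pool_size
    if ph or pw:
        x = np.pad(x, ((0, ph), (0, pw)), constant_values=-np.inf)
    oh, ow = x.shape[0] // pool_size, x.shape[1] // pool_size
    return x.reshape(oh, pool_size, ow, pool_size).max(axis=(1, 3))


def sgd_step(params: np.ndarray, grads: np.ndarray, lr: float) -> np.ndarray:
    """Plain gradient-descent update ``params - lr * grads``."""
    return np.asarray(params, dtype=float) - lr * np.asarray(grads, dtype=float)


# ---------------------------------------------------------------------------
# Batched layers (internal; NHWC layout)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, ksize: int, stride: int) -> np.ndarray:
    # x: (N, H, W, C) -> (N, OH, OW, C, kh, kw)
    win = np.lib.stride_tricks.sliding_window_view(x, (ksize, ksize), axis=(1, 2))
    return win[:, ::stride, ::stride]


class _ConvLayer:
    def __init__(
        self, in_ch: int, n_filters: int, ksize: int, stride: int,
        rng: np.random.Generator,
    ):
        fan_in = in_ch * ksize * ksize
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (in_ch, ksize, ksize, n_filters))
        self.b = np.zeros(n_filters)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)
        self.ksize = ksize
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._col = _im2col(x, self.ksize, self.stride)  # (N,OH,OW,C,kh,kw)
        self._in_shape = x.shape
        wmat = self.w.reshape(-1, self.w.shape[-1])
        n, oh, ow = self._col.shape[:3]
        out = self._col.reshape(n, oh, ow, -1) @ wmat + self.b
        return out

    def backward(self, dout: np.ndarray, lr: float, momentum: float = 0.0) -> np.ndarray:
        n, oh, ow, f = dout.shape
        col_flat = self._col.reshape(n * oh * ow, -1)
        dw = (col_flat.T @ dout.reshape(n * oh * ow, f)).reshape(self.w.shape)
        db = dout.sum(axis=(0, 1, 2))
        wmat = self.w.reshape(-1, f)
        dcol = (dout.reshape(-1, f) @ wmat.T).reshape(self._col.shape)
        dx = np.zeros(self._in_shape)
        s, k = self.stride, self.ksize
        for i in range(k):
            for j in range(k):
                dx[:, i : i + s * oh : s, j : j + s * ow : s, :] += dcol[:, :, :, :, i, j]
        self.vw = momentum * self.vw - lr * dw
        self.vb = momentum * self.vb - lr * db
        self.w = self.w + self.vw
        self.b = self.b + self.vb
        return dx


class _ReluLayer:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray, lr: float, momentum: float = 0.0) -> np.ndarray:
        return dout * self._mask


class _PoolLayer:
    def __init__(self, pool_size: int):
        self.p = pool_size

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.p
        n, h, w, c = x.shape
        ph, pw = (-h) % p, (-w) % p
        self._in_shape = x.shape
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), constant_values=-np.inf)
        self._pad_shape = x.shape
        oh, ow = x.shape[1] // p, x.shape[2] // p
        xr = x.reshape(n, oh, p, ow, p, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, oh, ow, c, p * p)
        self._argmax = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray, lr: float, momentum: float = 0.0) -> np.ndarray:
        p = self.p
        n, oh, ow, c = dout.shape
        dxr = np.zeros((n, oh, ow, c, p * p))
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dx = (
            dxr.reshape(n, oh, ow, c, p, p)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(self._pad_shape)
        )
        h, w = self._in_shape[1:3]
        return dx[:, :h, :w, :]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class CompactCnnExtractor:
    """From-scratch CNN trained with SGD; features = penultimate layer."""

    def __init__(self, config: ExtractorConfig):
        if config.backend != "compact_cnn":
            raise ValueError(
                "only the compact_cnn backend is implemented without an "
                "optional deep-learning runtime"
            )
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.layers: list = []
        in_ch = 3
        for n_filters, ksize, stride in config.conv_blocks:
            self.layers.append(_ConvLayer(in_ch, n_filters, ksize, stride, rng))
            self.layers.append(_ReluLayer())
            self.layers.append(_PoolLayer(config.pool_size))
            in_ch = n_filters
        self.head_w = rng.normal(0.0, np.sqrt(1.0 / config.feature_dim), config.feature_dim)
        self.head_b = 0.0
        self.trained = False
        self._vhw = np.zeros_like(self.head_w)
        self._vhb = 0.0
        self.loss_history: list[float] = []
        self._train_rng = np.random.default_rng(config.seed + 1)

    # -- forward ----------------------------------------------------------

    def _features_batch(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        self._gap_in_shape = x.shape
        return x.mean(axis=(1, 2))  # global average pool -> (N, feature_dim)

    def _logits(self, feats: np.ndarray) -> np.ndarray:
        return feats @ self.head_w + self.head_b

    def prepare_input(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Zero the background and resize to the network's input size.

        Lesion pixels are centered and rescaled (``2 * (x - 0.5)``) so the
        masked input is roughly zero-mean, which conditions SGD far
        better than raw [0, 1] intensities over a mostly-zero background.
        """
        from skimage.transform import resize

        if mask.shape != image.shape[:2]:
            raise ValueError("mask dimensions must match the image")
        image = np.asarray(image, dtype=float)
        mask_f = np.asarray(mask, dtype=float)[..., None]
        masked = 2.0 * (image - 0.5) * mask_f
        s = self.config.input_size
        if masked.shape[:2] != (s, s):
            masked = resize(masked, (s, s, 3), anti_aliasing=True)
        return masked

    # -- training ---------------------------------------------------------

    def fit(self, x: np.ndarray, y: np.ndarray) -> list[float]:
        """Mini-batch SGD on binary cross-entropy; returns per-epoch loss."""
        cfg = self.config.sgd
        n = x.shape[0]
        epoch_losses: list[float] = []
        for _ in range(cfg.epochs):
            order = self._train_rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                feats = self._features_batch(xb)
                logits = self._logits(feats)
                p = _sigmoid(logits)
                eps = 1e-12
                loss = -np.mean(
                    yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps)
                )
                losses.append(loss)
                # Backward pass
                dlogits = (p - yb) / len(yb)
                dw = feats.T @ dlogits
                db = dlogits.sum()
                dfeat = np.outer(dlogits, self.head_w)
                self._vhw = cfg.momentum * self._vhw - cfg.learning_rate * dw
                self._vhb = cfg.momentum * self._vhb - cfg.learning_rate * db
                self.head_w = self.head_w + self._vhw
                self.head_b = float(self.head_b + self._vhb)
                nb, h, w, c = self._gap_in_shape
                dgap = np.broadcast_to(
                    dfeat[:, None, None, :] / (h * w), self._gap_in_shape
                )
                d = dgap
                for layer in reversed(self.layers):
                    d = layer.backward(d, cfg.learning_rate, cfg.momentum)
            epoch_losses.append(float(np.mean(losses)))
        self.loss_history.extend(epoch_losses)
        self.trained = True
        return epoch_losses

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        conv_idx = 0
        for layer in self.layers:
            if isinstance(layer, _ConvLayer):
                arrays[f"conv{conv_idx}_w"] = layer.w
                arrays[f"conv{conv_idx}_b"] = layer.b
                conv_idx += 1
        arrays["head_w"] = self.head_w
        arrays["head_b"] = np.array([self.head_b])
        arrays["conv_blocks"] = np.array(self.config.conv_blocks)
        arrays["meta"] = np.array(
            [self.config.pool_size, self.config.feature_dim,
             self.config.input_size, int(self.trained)]
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "CompactCnnExtractor":
        data = np.load(path)
        pool, fdim, isize, trained = (int(v) for v in data["meta"])
        blocks = tuple(tuple(int(v) for v in row) for row in data["conv_blocks"])
        config = ExtractorConfig(
            conv_blocks=blocks, pool_size=pool, feature_dim=fdim, input_size=isize
        )
        obj = cls(config)
        conv_idx = 0
        for layer in obj.layers:
            if isinstance(layer, _ConvLayer):
                layer.w = data[f"conv{conv_idx}_w"]
                layer.b = data[f"conv{conv_idx}_b"]
                conv_idx += 1
        obj.head_w = data["head_w"]
        obj.head_b = float(data["head_b"][0])
        obj.trained = bool(trained)
        return obj


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def train_extractor(
    dataset, masks, config: ExtractorConfig | None = None
) -> CompactCnnExtractor:
    """Train the compact CNN on labeled images with their lesion masks.

    ``dataset`` is a sequence of objects with ``.image`` and ``.label``
    attributes; ``masks`` the matching segmentation masks.  Requires both
    classes to be present.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = ExtractorConfig()
    labels = [item.label for item in dataset]
    if len(set(labels)) < 2:
        raise ValueError("training requires at least two classes")
    extractor = CompactCnnExtractor(config)
    x = np.stack(
        [
            extractor.prepare_input(item.image, mask)
            for item, mask in zip(dataset, masks)
        ]
    )
    y = np.array([1.0 if lab == "melanoma" else 0.0 for lab in labels])
    extractor.fit(x, y)
    return extractor


def extract_features(
    extractor: CompactCnnExtractor,
    image: np.ndarray,
    mask: np.ndarray,
    source_id: str = "",
) -> FeatureVector:
    """Masked forward pass returning the fixed-length feature vector."""
    if not extractor.trained:
        raise ValueError("extractor has not been trained")
    x = extractor.prepare_input(image, mask)[None]
    feats = extractor._features_batch(x)[0]
    return FeatureVector(values=feats, source_id=source_id)
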