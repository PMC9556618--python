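"""A NumPy U-Net for binary RNFL segmentation.

The architecture follows the Ronneberger encoder–decoder design: per encoder
level two 3×3 same-padding convolutions with ReLU, then 2×2 max-pooling
(halving the grid); a symmetric decoder with 2×2 up-convolutions, skip
concatenations from the matching encoder level, and two 3×3 convolutions;
finally a 1×1 convolution to a single logit channel squashed by a logistic
sigmoid. The default filter ladder is (16, 32, 64, 128, 256), so a 256×256
input reaches a 16×16 bottleneck.

Forward and backward passes are written directly in NumPy. Activations are
kept channels-last (N, H, W, C) and each 3×3 convolution is computed as nine
shifted matrix multiplications, which on a single CPU core is markedly
faster than an explicit im2col buffer at these small channel counts. The
optimizer is Adam and the loss binary cross-entropy on the logits. Training
is deterministic given the seed: all randomness flows through numpy
Generators, so two runs with the same data and configuration produce
bit-identical weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, DataError
from .images import BScanImage, RNFLMask
from .preprocess import (
    ScaleInfo,
    denoise_morphological,
    prepare_input,
    prepare_mask,
    restore_mask,
)


@dataclass(frozen=True)
class UNetConfig:
    """Structural hyper-parameters of the segmentation network."""

    encoder_filters: tuple[int, ...] = (16, 32, 64, 128, 256)
    input_size: int = 256
    in_channels: int = 1

    def __post_init__(self) -> None:
        f = tuple(self.encoder_filters)
        if len(f) < 2 or any(b <= a for a, b in zip(f, f[1:])):
            raise ConfigurationError(
                "encoder_filters must be strictly increasing, length >= 2"
            )
        levels = len(f)
        if self.input_size % (2 ** (levels - 1)) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by 2^{levels - 1}"
            )


@dataclass
class TrainConfig:
    """Optimisation settings; the loss is binary cross-entropy on logits."""

    train_fraction: float = 0.8
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 8
    seed: int = 0
    mask_threshold: float = 0.5
    denoise_kernel_px: int = 3
    restore_best: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if not 0.0 < self.mask_threshold < 1.0:
            raise ConfigurationError("mask_threshold must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")


# ---------------------------------------------------------------------------
# layer primitives — activations are (N, H, W, C) float32


class _Conv3x3:
    """3×3 same-padding convolution with fused ReLU, as nine shifted matmuls."""

    def __init__(self, cin: int, cout: int, relu: bool, rng: np.random.Generator):
        fan_in = 9 * cin
        std = np.sqrt(2.0 / fan_in) if relu else np.sqrt(1.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(3, 3, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.relu = relu
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        f = self.W.shape[-1]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.empty((n * h * w, f), dtype=np.float32)
        out[:] = self.b
        for i in range(3):
            for j in range(3):
                sl = np.ascontiguousarray(xp[:, i : i + h, j : j + w, :]).reshape(-1, c)
                out += sl @ self.W[i, j]
        out = out.reshape(n, h, w, f)
        if self.relu:
            mask = out > 0
            out = np.where(mask, out, np.float32(0.0))
        else:
            mask = None
        if train:
            self._cache = (xp, mask)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, mask = self._cache
        self._cache = None
        n, hp, wp, c = xp.shape
        h, w = hp - 2, wp - 2
        f = self.W.shape[-1]
        if mask is not None:
            dout = np.where(mask, dout, np.float32(0.0))
        df = dout.reshape(-1, f)
        self.dW = np.empty_like(self.W)
        self.db = df.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                sl = np.ascontiguousarray(xp[:, i : i + h, j : j + w, :]).reshape(-1, c)
                self.dW[i, j] = sl.T @ df
                dxp[:, i : i + h, j : j + w, :] += (df @ self.W[i, j].T).reshape(
                    n, h, w, c
                )
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class _Conv1x1:
    """1×1 convolution (a per-pixel linear map) producing the output logits."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(1.0 / cin)
        self.W = rng.normal(0.0, std, size=(cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        out = (x.reshape(-1, c) @ self.W + self.b).reshape(n, h, w, -1)
        if train:
            self._cache = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        n, h, w, c = x.shape
        f = self.W.shape[-1]
        df = dout.reshape(-1, f)
        self.dW = x.reshape(-1, c).T @ df
        self.db = df.sum(axis=0)
        return (df @ self.W.T).reshape(n, h, w, c)


class _MaxPool:
    """2×2 max-pooling with stride 2."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xr = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h // 2, w // 2, 4, c)
        )
        idx = xr.argmax(axis=3)
        out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._cache = (idx, (n, h, w, c))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._cache
        self._cache = None
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(dxr, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        return (
            dxr.reshape(n, h // 2, w // 2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h, w, c)
        )


class _UpConv:
    """2×2 up-convolution (transposed convolution with stride 2)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (4 * cin))
        self.W = rng.normal(0.0, std, size=(cin, 2, 2, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        f = self.W.shape[-1]
        tmp = (x.reshape(-1, c) @ self.W.reshape(c, 4 * f)).reshape(n, h, w, 2, 2, f)
        out = tmp.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * w, f) + self.b
        if train:
            self._cache = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self._cache = None
        n, h, w, c = x.shape
        f = self.W.shape[-1]
        dr = (
            dout.reshape(n, h, 2, w, 2, f)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(-1, 4 * f)
        )
        self.dW = (x.reshape(-1, c).T @ dr).reshape(self.W.shape)
        self.db = dout.sum(axis=(0, 1, 2))
        return (dr @ self.W.reshape(c, 4 * f).T).reshape(n, h, w, c)


# ---------------------------------------------------------------------------


class SegmentationModel:
    """U-Net encoder–decoder producing a single-channel probability map."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = tuple(config.encoder_filters)
        levels = len(f)

        self.enc: list[tuple[_Conv3x3, _Conv3x3]] = []
        c_prev = config.in_channels
        for lvl in range(levels):
            c1 = _Conv3x3(c_prev, f[lvl], relu=True, rng=rng)
            c2 = _Conv3x3(f[lvl], f[lvl], relu=True, rng=rng)
            self.enc.append((c1, c2))
            c_prev = f[lvl]
        self.pools = [_MaxPool() for _ in range(levels - 1)]

        self.ups: list[_UpConv] = []
        self.dec: list[tuple[_Conv3x3, _Conv3x3]] = []
        for lvl in range(levels - 2, -1, -1):
            self.ups.append(_UpConv(f[lvl + 1], f[lvl], rng))
            d1 = _Conv3x3(2 * f[lvl], f[lvl], relu=True, rng=rng)
            d2 = _Conv3x3(f[lvl], f[lvl], relu=True, rng=rng)
            self.dec.append((d1, d2))
        self.out_conv = _Conv1x1(f[0], 1, rng=rng)

    # -- parameter bookkeeping ---------------------------------------------

    def _layers(self):
        for c1, c2 in self.enc:
            yield c1
            yield c2
        for up, (d1, d2) in zip(self.ups, self.dec):
            yield up
            yield d1
            yield d2
        yield self.out_conv

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend([layer.dW, layer.db])
        return out

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W) or (N, H, W, C) float32 → logits of the same spatial dims."""
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4:
            raise ContractError("network input must be (N, H, W) or (N, H, W, C)")
        levels = len(self.enc)
        skips = []
        h = np.ascontiguousarray(x, dtype=np.float32)
        for lvl in range(levels):
            c1, c2 = self.enc[lvl]
            h = c2.forward(c1.forward(h, train), train)
            if lvl < levels - 1:
                skips.append(h)
                h = self.pools[lvl].forward(h, train)
        self._skip_channels = [s.shape[-1] for s in skips]
        for i, (up, (d1, d2)) in enumerate(zip(self.ups, self.dec)):
            h = up.forward(h, train)
            skip = skips[-(i + 1)]
            h = np.concatenate([skip, h], axis=-1)
            h = d2.forward(d1.forward(h, train), train)
        return self.out_conv.forward(h, train)[..., 0]

    def backward(self, dlogits: np.ndarray) -> None:
        levels = len(self.enc)
        d = self.out_conv.backward(dlogits[..., None])
        dskips: list[np.ndarray | None] = [None] * (levels - 1)
        for i in range(len(self.dec) - 1, -1, -1):
            up, (d1, d2) = self.ups[i], self.dec[i]
            d = d1.backward(d2.backward(d))
            nskip = self._skip_channels[-(i + 1)]
            dskip, dup = d[..., :nskip], d[..., nskip:]
            dskips[levels - 2 - i] = dskip
            d = up.backward(np.ascontiguousarray(dup))
        for lvl in range(levels - 1, -1, -1):
            c1, c2 = self.enc[lvl]
            if lvl < levels - 1:
                d = self.pools[lvl].backward(d)
                d = d + dskips[lvl]
            d = c1.backward(c2.backward(d))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability map in (0, 1) with the input's spatial dimensions."""
        z = self.forward_logits(x, train=False)
        return 1.0 / (1.0 + np.exp(-z))

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a JSON sidecar with the configuration."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "encoder_filters": list(self.config.encoder_filters),
            "input_size": self.config.input_size,
            "in_channels": self.config.in_channels,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        config = UNetConfig(
            encoder_filters=tuple(sidecar["encoder_filters"]),
            input_size=sidecar["input_size"],
            in_channels=sidecar["in_channels"],
        )
        model = cls(config, seed=0)
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.parameters()):
                p[...] = data[f"p{i}"]
        return model


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> SegmentationModel:
    """Construct a randomly initialised U-Net (He-normal weights, seeded)."""
    return SegmentationModel(config or UNetConfig(), seed=seed)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits.

    Uses the numerically stable softplus form; the gradient is
    (sigmoid(z) − y) / N.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((1.0 / (1.0 + np.exp(-z))) - y) / z.size
    return loss, grad.astype(np.float32)


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# training on a dataset manifest


def _load_training_arrays(dataset, tc: TrainConfig, target: int):
    from .images import load_bscan, load_mask

    frame = dataset.frame
    if len(frame) == 0:
        raise DataError("dataset manifest is empty")
    xs, ys, ids = [], [], []
    for _, row in frame.iterrows():
        image = load_bscan(dataset.root / row.image, scan_id=row.scan_id)
        mask = load_mask(dataset.root / row["mask"], scan_id=row.scan_id)
        if mask.pixels.shape != image.pixels.shape:
            raise DataError(
                f"mask misaligned with image for scan_id={row.scan_id!r}: "
                f"{mask.pixels.shape} vs {image.pixels.shape}"
            )
        image = denoise_morphological(image, tc.denoise_kernel_px)
        x, _ = prepare_input(image, target)
        y = prepare_mask(mask, target)
        xs.append(x)
        ys.append(y)
        ids.append(row.scan_id)
    return np.stack(xs), np.stack(ys), ids


def split_scan_ids(scan_ids, train_fraction: float, seed: int):
    """Shuffle scan identifiers and split train/validation by scan, not pixel."""
    rng = np.random.default_rng(seed)
    ids = list(scan_ids)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = [ids[i] for i in order[:n_train]]
    val = [ids[i] for i in order[n_train:]]
    return train, val


def train_model(
    model: SegmentationModel, dataset, tc: TrainConfig
) -> tuple[SegmentationModel, pd.DataFrame]:
    """Fit the network on an image/mask manifest; returns (model, history).

    Scans are split into training and validation sets at the scan level
    (never mixing one scan's pixels across the split); mini-batch order is
    reshuffled each epoch from the training seed. History holds one row per
    epoch with the mean training loss and the validation loss. With
    ``restore_best`` (the default) the returned weights are those of the
    epoch with the lowest validation loss, so a late optimisation spike
    cannot degrade the delivered model.
    """
    if len(dataset.frame) < 2:
        raise DataError("training requires at least 2 image/mask pairs")
    target = model.config.input_size
    x, y, ids = _load_training_arrays(dataset, tc, target)
    train_ids, val_ids = split_scan_ids(ids, tc.train_fraction, tc.seed)
    id_index = {s: i for i, s in enumerate(ids)}
    tr = np.array([id_index[s] for s in train_ids])
    va = np.array([id_index[s] for s in val_ids])

    opt = _Adam(model.parameters(), lr=tc.learning_rate)
    rng = np.random.default_rng(tc.seed + 1)
    history = []
    best_val = np.inf
    best_params: list[np.ndarray] | None = None
    for epoch in range(tc.epochs):
        order = rng.permutation(len(tr))
        losses = []
        for start in range(0, len(tr), tc.batch_size):
            idx = tr[order[start : start + tc.batch_size]]
            logits = model.forward_logits(x[idx], train=True)
            loss, dlogits = bce_with_logits(logits, y[idx])
            model.backward(dlogits)
            opt.step(model.gradients())
            losses.append(loss)
        val_losses = []
        for start in range(0, len(va), tc.batch_size):
            idx = va[start : start + tc.batch_size]
            logits = model.forward_logits(x[idx], train=False)
            loss, _ = bce_with_logits(logits, y[idx])
            val_losses.append(loss * len(idx))
        train_loss = float(np.mean(losses))
        val_loss = float(np.sum(val_losses) / max(len(va), 1))
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise DataError(f"non-finite loss at epoch {epoch}")
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if tc.restore_best and val_loss < best_val:
            best_val = val_loss
            best_params = [p.copy() for p in model.parameters()]
    if tc.restore_best and best_params is not None:
        for p, best in zip(model.parameters(), best_params):
            p[...] = best
    return model, pd.DataFrame(history)


def predict_mask(
    model: SegmentationModel,
    image: BScanImage,
    scale: ScaleInfo | None = None,
    threshold: float = 0.5,
) -> RNFLMask:
    """Segment one (already denoised) B-scan and map the mask back to its grid.

    The probability map is thresholded on the network grid, then un-padded
    and un-scaled through the ScaleInfo; the result is strictly binary on
    the original image grid.
    """
    x, info = prepare_input(image, model.config.input_size)
    if scale is not None and scale != info:
        raise ContractError(
            "provided ScaleInfo is inconsistent with the image dimensions"
        )
    proba = model.predict_proba(x[None])[0]
    grid_mask = proba >= threshold
    restored = restore_mask(grid_mask, info)
    return RNFLMask(
        pixels=restored.astype(np.uint8),
        axial_spacing_um=image.axial_spacing_um,
        eye=image.eye,
        scan_id=image.scan_id,
    )


def expected_parameter_count(config: UNetConfig) -> int:
    """Closed-form parameter count: Σ (k·k·c_in + 1)·c_out over all layers.

    Kept separate from the model so tests can compare an independent count
    against the arrays actually allocated.
    """
    f = tuple(config.encoder_filters)
    total = 0
    c_prev = config.in_channels
    for c in f:
        total += (9 * c_prev + 1) * c + (9 * c + 1) * c
        c_prev = c
    for lvl in range(len(f) - 2, -1, -1):
        total += (4 * f[lvl + 1] + 1) * f[lvl]  # 2×2 up-convolution
        total += (9 * 2 * f[lvl] + 1) * f[lvl] + (9 * f[lvl] + 1) * f[lvl]
    total += (1 * f[0] + 1) * 1
    return total
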