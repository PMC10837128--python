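"""Virtual staining: predict BC / sinusoid channels from phalloidin.

A compact 3D convolutional encoder-decoder (U-Net topology: 3
encoder-decoder levels, 3x3x3 convolutions, skip connections, a linear
single-channel regression head) implemented directly on numpy arrays with
explicit backpropagation.  Convolutions are evaluated as im2col matrix
products so the heavy lifting runs in BLAS; training uses stochastic
gradient descent with momentum 0.9 and learning rate 0.05 minimising mean
squared error, and keeps the weights with the best validation loss.

All arrays are ``float32`` in ``(C, z, y, x)`` layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Lobule3DError, VoxelGrid, logger


class TrainingDivergedError(Lobule3DError):
    """Loss became non-finite during optimisation."""


class EmptyPatchSetError(Lobule3DError):
    """No training patches available."""


class PatchSizeError(Lobule3DError):
    """Image smaller than the requested patch/tile size."""


# ---------------------------------------------------------------------------
# Configuration / containers
# ---------------------------------------------------------------------------


@dataclass
class UNet3DConfig:
    """Hyperparameters of the 3D regression network.

    Defaults follow the reference training recipe (3 levels, 64 filters of
    3x3x3, batches of 8 64^3 patches, SGD momentum 0.9, learning rate 0.05,
    100 epochs); tests and desk-scale runs shrink ``filters``/``epochs``.
    """

    n_blocks: int = 3
    filters: int = 64
    patch_size: int = 64
    batch_size: int = 8
    learning_rate: float = 0.05
    momentum: float = 0.9
    epochs: int = 100
    seed: int = 0
    augmentation: str = "none"  # recorded in the train report

    def __post_init__(self) -> None:
        if self.patch_size % (2**self.n_blocks) != 0:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by 2^{self.n_blocks}"
            )
        for v in (self.filters, self.patch_size, self.batch_size,
                  self.learning_rate, self.momentum, self.epochs):
            if not v > 0:
                raise ValueError("all hyperparameters must be positive")


@dataclass
class PatchSet:
    """Paired input/target patches on a non-overlapping grid."""

    train_x: np.ndarray  # (n, p, p, p) float32
    train_y: np.ndarray
    val_x: np.ndarray
    val_y: np.ndarray
    patch_size: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_train(self) -> int:
        return len(self.train_x)

    @property
    def n_val(self) -> int:
        return len(self.val_x)


@dataclass
class TrainReport:
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    seed: int
    augmentation: str = "none"


# ---------------------------------------------------------------------------
# Layers (forward + explicit backward)
# ---------------------------------------------------------------------------


class _Conv3d:
    """Same-padding 3D convolution via im2col; kernel 3 (or 1 for the head)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k**3
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        self._shape = x.shape[1:]
        if k == 1:
            col = x.reshape(self.c_in, -1).T
        else:
            pad = k // 2
            xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
            v = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
            # (C, D, H, W, k, k, k) -> (D*H*W, C*k^3)
            col = (
                v.transpose(1, 2, 3, 0, 4, 5, 6)
                .reshape(-1, self.c_in * k**3)
                .astype(np.float32)
            )
        self._col = col
        out = col @ self.W + self.b
        return np.ascontiguousarray(out.T.reshape(self.c_out, *self._shape))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        d, h, w = self._shape
        dy_flat = dy.reshape(self.c_out, -1).T.astype(np.float32)
        self.gW += self._col.T @ dy_flat
        self.gb += dy_flat.sum(axis=0)
        dcol = dy_flat @ self.W.T
        self._col = None
        if k == 1:
            return np.ascontiguousarray(dcol.T.reshape(self.c_in, d, h, w))
        pad = k // 2
        dxp = np.zeros((self.c_in, d + 2 * pad, h + 2 * pad, w + 2 * pad), np.float32)
        dcol = dcol.reshape(d, h, w, self.c_in, k, k, k)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, i : i + d, j : j + h, l : l + w] += dcol[
                        :, :, :, :, i, j, l
                    ].transpose(3, 0, 1, 2)
        return dxp[:, pad : pad + d, pad : pad + h, pad : pad + w]

    def params(self):
        return [(self.W, self.gW, self.vW), (self.b, self.gb, self.vb)]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dy, 0.0)
        self._mask = None
        return out


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        blocks = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(
            c, d // 2, h // 2, w // 2, 8
        )
        self._idx = blocks.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(blocks, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        out = np.zeros((c, d // 2, h // 2, w // 2, 8), np.float32)
        np.put_along_axis(out, self._idx[..., None], dy[..., None], axis=-1)
        out = out.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        out = out.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w)
        self._idx = None
        return out


class _UpConv2:
    """2x2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.W = (
            rng.standard_normal((c_in, c_out * 8)) * np.sqrt(2.0 / c_in)
        ).astype(np.float32)
        self.b = np.zeros(c_out, np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        self._x = x
        out = (x.reshape(c, -1).T @ self.W).reshape(d, h, w, self.c_out, 2, 2, 2)
        out = out + self.b[None, None, None, :, None, None, None]
        out = out.transpose(3, 0, 4, 1, 5, 2, 6).reshape(
            self.c_out, 2 * d, 2 * h, 2 * w
        )
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._x.shape
        blocks = dy.reshape(self.c_out, d, 2, h, 2, w, 2).transpose(
            1, 3, 5, 0, 2, 4, 6
        )
        dflat = blocks.reshape(-1, self.c_out * 8).astype(np.float32)
        x_flat = self._x.reshape(c, -1)
        self.gW += x_flat @ dflat
        self.gb += blocks.sum(axis=(0, 1, 2, 4, 5, 6))
        dx = (dflat @ self.W.T).T.reshape(c, d, h, w)
        self._x = None
        return np.ascontiguousarray(dx)

    def params(self):
        return [(self.W, self.gW, self.vW), (self.b, self.gb, self.vb)]


class UNet3D:
    """3-level convolutional encoder-decoder regressor on single-channel volumes."""

    def __init__(self, config: UNet3DConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.filters
        self.enc = [_Conv3d(1 if i == 0 else f, f, 3, rng) for i in range(config.n_blocks)]
        self.bottleneck = _Conv3d(f, f, 3, rng)
        self.up = [_UpConv2(f, f, rng) for _ in range(config.n_blocks)]
        self.dec = [_Conv3d(2 * f, f, 3, rng) for _ in range(config.n_blocks)]
        self.head = _Conv3d(f, 1, 1, rng)
        self.enc_relu = [_ReLU() for _ in self.enc]
        self.bot_relu = _ReLU()
        self.dec_relu = [_ReLU() for _ in self.dec]
        self.pools = [_MaxPool2() for _ in self.enc]

    # -- forward/backward over one (1, d, h, w) sample
    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for conv, relu, pool in zip(self.enc, self.enc_relu, self.pools):
            h = relu.forward(conv.forward(h))
            skips.append(h)
            h = pool.forward(h)
        h = self.bot_relu.forward(self.bottleneck.forward(h))
        for up, conv, relu, skip in zip(
            reversed(self.up), reversed(self.dec), reversed(self.dec_relu),
            reversed(skips),
        ):
            h = up.forward(h)
            h = np.concatenate([h, skip], axis=0)
            h = relu.forward(conv.forward(h))
        return self.head.forward(h)

    def backward(self, dy: np.ndarray) -> None:
        f = self.config.filters
        dh = self.head.backward(dy)
        dskips = []
        for up, conv, relu in zip(self.up, self.dec, self.dec_relu):
            dh = conv.backward(relu.backward(dh))
            dskips.append(dh[f:])
            dh = up.backward(dh[:f])
        dh = self.bottleneck.backward(self.bot_relu.backward(dh))
        for conv, relu, pool, dskip in zip(
            reversed(self.enc), reversed(self.enc_relu), reversed(self.pools),
            reversed(dskips),
        ):
            dh = pool.backward(dh) + dskip
            dh = conv.backward(relu.backward(dh))

    def _layers(self):
        return self.enc + [self.bottleneck] + self.up + self.dec + [self.head]

    def zero_grad(self) -> None:
        for layer in self._layers():
            for _, g, _ in layer.params():
                g[...] = 0.0

    def sgd_step(self, lr: float, momentum: float, scale: float) -> None:
        for layer in self._layers():
            for w, g, v in layer.params():
                v *= momentum
                v -= lr * scale * g
                w += v

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self._layers()):
            state[f"W{i}"] = layer.W.copy()
            state[f"b{i}"] = layer.b.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self._layers()):
            layer.W[...] = state[f"W{i}"]
            layer.b[...] = state[f"b{i}"]


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------


def extract_patches(
    input_grid: VoxelGrid,
    target_grid: VoxelGrid,
    patch_size: int,
    val_fraction: float = 0.1,
    seed: int = 0,
    max_patches: int | None = None,
) -> PatchSet:
    """Tile paired volumes into non-overlapping patches and split train/val.

    The grid starts at the origin; trailing remainders are discarded.  Each
    voxel belongs to at most one patch, and the split is a seeded
    permutation, so the same seed reproduces the same split.
    ``max_patches`` keeps a seeded random subset of the tiling.
    """
    x = np.asarray(input_grid.data, np.float32)
    y = np.asarray(target_grid.data, np.float32)
    if x.shape != y.shape:
        raise ValueError("input and target must share shape")
    p = patch_size
    if any(s < p for s in x.shape):
        raise PatchSizeError(f"image {x.shape} smaller than patch {p}")
    nz, ny, nx_ = (s // p for s in x.shape)
    xs, ys = [], []
    for i in range(nz):
        for j in range(ny):
            for k in range(nx_):
                sl = (
                    slice(i * p, (i + 1) * p),
                    slice(j * p, (j + 1) * p),
                    slice(k * p, (k + 1) * p),
                )
                xs.append(x[sl])
                ys.append(y[sl])
    xs_arr = np.stack(xs)
    ys_arr = np.stack(ys)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(xs_arr))
    if max_patches is not None:
        order = order[:max_patches]
    n_val = int(round(val_fraction * len(order)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    return PatchSet(
        train_x=xs_arr[train_idx],
        train_y=ys_arr[train_idx],
        val_x=xs_arr[val_idx],
        val_y=ys_arr[val_idx],
        patch_size=p,
        provenance={"n_total": len(xs_arr), "seed": seed},
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_virtual_stainer(
    patches: PatchSet, config: UNet3DConfig
) -> tuple[UNet3D, TrainReport]:
    """Train the regressor with SGD + momentum on mean squared error.

    The model with the best validation loss is retained (training-loss best
    when there is no validation split).  Raises
    :class:`TrainingDivergedError` if the loss becomes non-finite.
    """
    if patches.n_train == 0:
        raise EmptyPatchSetError("no training patches")
    model = UNet3D(config)
    rng = np.random.default_rng(config.seed + 1)
    train_losses, val_losses = [], []
    best_state = model.state_dict()
    best_val = np.inf
    best_epoch = 0
    for epoch in range(config.epochs):
        order = rng.permutation(patches.n_train)
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            model.zero_grad()
            batch_loss = 0.0
            for i in idx:
                x = patches.train_x[i][None]
                y = patches.train_y[i][None]
                pred = model.forward(x)
                resid = pred - y
                batch_loss += float(np.mean(resid**2))
                model.backward((2.0 / resid.size) * resid.astype(np.float32))
            if not np.isfinite(batch_loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch + 1}"
                )
            model.sgd_step(config.learning_rate, config.momentum, 1.0 / len(idx))
            epoch_loss += batch_loss
        train_loss = epoch_loss / patches.n_train
        val_loss = _eval_loss(model, patches.val_x, patches.val_y)
        monitor = val_loss if patches.n_val else train_loss
        train_losses.append(train_loss)
        val_losses.append(val_loss)
        if not np.isfinite(train_loss):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch + 1}")
        if monitor < best_val:
            best_val = monitor
            best_state = model.state_dict()
            best_epoch = epoch + 1
        logger.info(
            "epoch %d/%d: train mse %.3g val mse %.3g",
            epoch + 1, config.epochs, train_loss, val_loss,
        )
    model.load_state_dict(best_state)
    report = TrainReport(
        train_loss=train_losses,
        val_loss=val_losses,
        best_epoch=best_epoch,
        seed=config.seed,
        augmentation=config.augmentation,
    )
    return model, report


def _eval_loss(model: UNet3D, xs: np.ndarray, ys: np.ndarray) -> float:
    if len(xs) == 0:
        return float("nan")
    total = 0.0
    for x, y in zip(xs, ys):
        pred = model.forward(x[None])
        total += float(np.mean((pred - y[None]) ** 2))
    return total / len(xs)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def predict_virtual_channel(
    model: UNet3D,
    grid: VoxelGrid,
    tile: int | None = None,
    overlap: int = 8,
) -> VoxelGrid:
    """Predict a virtual channel by tiled inference with linear blending.

    The volume is processed in ``tile``-sized cubes overlapping by
    ``overlap`` voxels; overlapping predictions are averaged with linear
    ramp weights to avoid seams.  A volume that fits in one tile is
    processed in a single pass.
    """
    tile = tile or model.config.patch_size
    step = 2**model.config.n_blocks
    x = np.asarray(grid.data, np.float32)
    # pad so every dimension is a multiple of the down-sampling factor
    pads = [(0, (-s) % step) for s in x.shape]
    xp = np.pad(x, pads, mode="reflect") if any(p[1] for p in pads) else x
    shape = xp.shape
    if all(s <= tile for s in shape):
        out = model.forward(xp[None])[0]
    else:
        out = np.zeros(shape, np.float32)
        weight = np.zeros(shape, np.float32)
        w_tile = _blend_weights(tile, overlap)
        stride = tile - overlap
        starts = [
            sorted({min(s0, max(0, n - tile)) for s0 in range(0, n, stride)})
            for n in shape
        ]
        for z0 in starts[0]:
            for y0 in starts[1]:
                for x0 in starts[2]:
                    sl = (
                        slice(z0, min(z0 + tile, shape[0])),
                        slice(y0, min(y0 + tile, shape[1])),
                        slice(x0, min(x0 + tile, shape[2])),
                    )
                    block = xp[sl]
                    pred = model.forward(block[None])[0]
                    w = w_tile[: block.shape[0], : block.shape[1], : block.shape[2]]
                    out[sl] += pred * w
                    weight[sl] += w
        out /= np.maximum(weight, 1e-12)
    out = out[: x.shape[0], : x.shape[1], : x.shape[2]]
    return VoxelGrid(out, grid.voxel_size_um, grid.origin_um)


def _blend_weights(tile: int, overlap: int) -> np.ndarray:
    ramp = np.ones(tile, np.float32)
    if overlap > 0:
        edge = np.linspace(1.0 / (overlap + 1), 1.0, overlap, dtype=np.float32)
        ramp[:overlap] = edge
        ramp[-overlap:] = edge[::-1]
    return ramp[:, None, None] * ramp[None, :, None] * ramp[None, None, :]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


class DegenerateTruthError(Lobule3DError):
    """Truth image has an empty foreground or background under Otsu."""


def evaluate_prediction(
    pred: VoxelGrid,
    truth: VoxelGrid,
    line: tuple | None = None,
) -> dict:
    """Score a virtual channel against its reference.

    Returns voxelwise Pearson r, the signal-to-background ratio (mean
    intensity over the truth foreground / mean over the truth background,
    foreground by Otsu of the truth), and, if ``line`` (two (z, y, x) voxel
    endpoints) is given, intensity profiles sampled along it at voxel pitch.
    """
    from skimage.filters import threshold_otsu
    from scipy.ndimage import map_coordinates

    p = np.asarray(pred.data, np.float32)
    t = np.asarray(truth.data, np.float32)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must share shape")
    r = float(np.corrcoef(p.ravel(), t.ravel())[0, 1])
    if t.min() == t.max():
        raise DegenerateTruthError("constant truth image")
    thr = threshold_otsu(t)
    fg = t > thr
    if not fg.any() or fg.all():
        raise DegenerateTruthError("empty foreground or background under Otsu")
    sbr = float(p[fg].mean() / max(p[~fg].mean(), 1e-12))
    out = {"pearson_r": r, "signal_to_background": sbr}
    if line is not None:
        a, b = np.asarray(line[0], float), np.asarray(line[1], float)
        n = max(2, int(np.ceil(np.linalg.norm(b - a))) + 1)
        ts = np.linspace(0, 1, n)
        coords = a[:, None] * (1 - ts) + b[:, None] * ts
        out["intensity_profiles"] = {
            "pred": map_coordinates(p, coords, order=1),
            "truth": map_coordinates(t, coords, order=1),
            "positions_um": ts * np.linalg.norm(b - a) * truth.voxel_size_um,
        }
    return out


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_model(
    model: UNet3D, path: str | Path, norm_state: dict | None = None
) -> None:
    """Save weights + config + normalization state as a single .npz file."""
    state = model.state_dict()
    meta = {"config": asdict(model.config), "norm_state": norm_state or {}}
    np.savez_compressed(Path(path), __meta__=np.frombuffer(
        __import__("json").dumps(meta).encode(), dtype=np.uint8
    ), **state)


def load_model(path: str | Path) -> tuple[UNet3D, dict]:
    import json

    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = UNet3D(UNet3DConfig(**meta["config"]))
    model.load_state_dict(state)
    return model, meta.get("norm_state", {})
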