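"""Per-voxel blob likelihood from a small U-Net, implemented in numpy.

The network is the global constraint of the detector: an encoder-decoder
with skip connections that maps a noisy grayscale image to a probability
map in [0, 1], trained with binary cross entropy on noise-corrupted binary
label images (mask + N(0, 0.01), clipped to [0, 1]). The architecture is
deliberately small — default 3 resolution levels, 16 base channels, one
3×3 convolution per block — so it trains on synthetic fixtures in minutes
on one CPU. Forward and backward passes, and the Adam optimizer, are
written directly against numpy arrays; every random draw flows from a
single integer seed, so training is exactly reproducible.

3D volumes are handled slice-wise along z: the probability map U(x,y,z) is
the stack of 2D predictions, one per slice.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image_io import ImageGrid

__all__ = [
    "ProbabilityMap",
    "TrainingPair",
    "ModelState",
    "TrainConfig",
    "AugmentConfig",
    "bce_loss",
    "make_training_pair",
    "augment",
    "train",
    "predict_probability_map",
    "save_model",
    "load_model",
]

_EPS = 1e-7


@dataclass
class ProbabilityMap:
    """Blob likelihood per voxel, same extent as the source image."""

    data: np.ndarray
    model_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValueError("probability values must lie in [0, 1]")


@dataclass
class TrainingPair:
    """Noisy input image and its binary label mask."""

    input: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.input = np.asarray(self.input, dtype=float)
        self.label = np.asarray(self.label)
        if self.input.shape != self.label.shape:
            raise ValueError("input and label shapes differ")
        uniq = np.unique(self.label)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("label must be strictly binary")
        self.label = self.label.astype(float)


def bce_loss(predicted: np.ndarray, label: np.ndarray) -> float:
    """Mean binary cross entropy with predictions clamped to [ε, 1−ε]."""
    predicted = np.asarray(predicted, dtype=float)
    label = np.asarray(label, dtype=float)
    if predicted.shape != label.shape:
        raise ValueError("prediction and label shapes differ")
    p = np.clip(predicted, _EPS, 1.0 - _EPS)
    return float(-np.mean(label * np.log(p) + (1.0 - label) * np.log(1.0 - p)))


def make_training_pair(
    label_mask: np.ndarray,
    noise_mu: float = 0.0,
    noise_var: float = 0.01,
    seed: int = 0,
) -> TrainingPair:
    """Corrupt a binary mask with Gaussian noise: clip(mask + N(μ, σ²), 0, 1)."""
    if noise_var < 0:
        raise ValueError("noise variance must be >= 0")
    mask = np.asarray(label_mask)
    noisy = mask.astype(float)
    if noise_var > 0 or noise_mu != 0.0:
        rng = np.random.default_rng(seed)
        noisy = noisy + rng.normal(noise_mu, np.sqrt(noise_var), mask.shape)
    return TrainingPair(np.clip(noisy, 0.0, 1.0), mask.astype(float))


# ---------------------------------------------------------------------------
# data augmentation


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the random geometric transform (2D).

    All ranges are symmetric about the identity; setting every range to
    zero and disabling the flip yields the identity transform exactly.
    """

    rotation_deg: float = 15.0
    shift_frac: float = 0.1
    shear_deg: float = 8.0
    zoom_range: tuple[float, float] = (0.9, 1.1)
    hflip: bool = True


def augment(pair: TrainingPair, seed: int, config: AugmentConfig | None = None) -> TrainingPair:
    """Apply one random geometric transform identically to input and label.

    Rotation/shift/shear/zoom are combined into a single affine resampling
    (bilinear for the input, with the label re-binarized at 0.5); the
    horizontal flip is exact. An identity draw returns the pair unchanged.
    """
    from scipy import ndimage

    if pair.input.ndim != 2:
        raise ValueError("augmentation operates on 2D pairs")
    config = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
    shift = rng.uniform(-config.shift_frac, config.shift_frac, 2) * pair.input.shape
    shear = np.deg2rad(rng.uniform(-config.shear_deg, config.shear_deg))
    zoom = rng.uniform(*config.zoom_range)
    flip = bool(config.hflip and rng.random() < 0.5)

    inp, lab = pair.input, pair.label
    if flip:
        inp, lab = inp[:, ::-1], lab[:, ::-1]

    if theta == 0.0 and shear == 0.0 and zoom == 1.0 and not np.any(shift):
        return TrainingPair(inp.copy(), lab.copy())

    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    shear_m = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    matrix = (rot @ shear_m) / zoom
    center = (np.asarray(pair.input.shape) - 1) / 2.0
    offset = center - matrix @ (center + shift)
    warped_in = ndimage.affine_transform(inp, matrix, offset=offset, order=1, mode="constant")
    warped_lab = ndimage.affine_transform(lab, matrix, offset=offset, order=1, mode="constant")
    return TrainingPair(np.clip(warped_in, 0.0, 1.0), (warped_lab > 0.5).astype(float))


# ---------------------------------------------------------------------------
# network layers (single-sample, channels-first arrays)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C,H,W) -> (H*W, C*9) patches of the zero-padded input."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (C,H,W,3,3)
    return win.transpose(1, 2, 0, 3, 4).reshape(h * w, c * 9)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    c, h, w = shape
    dxp = np.zeros((c, h + 2, w + 2))
    d = dcols.reshape(h, w, c, 3, 3)
    for i in range(3):
        for j in range(3):
            dxp[:, i : i + h, j : j + w] += d[:, :, :, i, j].transpose(2, 0, 1)
    return dxp[:, 1:-1, 1:-1]


class _Conv3x3:
    def __init__(self, name: str, cin: int, cout: int):
        self.name, self.cin, self.cout = name, cin, cout

    def init(self, rng: np.random.Generator, params: dict) -> None:
        fan_in = self.cin * 9
        params[self.name + ".W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, self.cout))
        params[self.name + ".b"] = np.zeros(self.cout)

    def forward(self, x: np.ndarray, params: dict, cache: dict) -> np.ndarray:
        cols = _im2col(x)
        cache[self.name] = (cols, x.shape)
        y = cols @ params[self.name + ".W"] + params[self.name + ".b"]
        h, w = x.shape[1:]
        return y.reshape(h, w, self.cout).transpose(2, 0, 1)

    def backward(self, dy: np.ndarray, params: dict, cache: dict, grads: dict) -> np.ndarray:
        cols, xshape = cache[self.name]
        dyf = dy.transpose(1, 2, 0).reshape(-1, self.cout)
        grads[self.name + ".W"] = cols.T @ dyf
        grads[self.name + ".b"] = dyf.sum(axis=0)
        return _col2im(dyf @ params[self.name + ".W"].T, xshape)


class _Conv1x1:
    def __init__(self, name: str, cin: int, cout: int):
        self.name, self.cin, self.cout = name, cin, cout

    def init(self, rng: np.random.Generator, params: dict) -> None:
        params[self.name + ".W"] = rng.normal(0.0, np.sqrt(2.0 / self.cin), (self.cin, self.cout))
        params[self.name + ".b"] = np.zeros(self.cout)

    def forward(self, x: np.ndarray, params: dict, cache: dict) -> np.ndarray:
        c, h, w = x.shape
        flat = x.reshape(c, -1).T
        cache[self.name] = flat
        y = flat @ params[self.name + ".W"] + params[self.name + ".b"]
        return y.T.reshape(self.cout, h, w)

    def backward(self, dy: np.ndarray, params: dict, cache: dict, grads: dict) -> np.ndarray:
        flat = cache[self.name]
        c, h, w = dy.shape
        dyf = dy.reshape(c, -1).T
        grads[self.name + ".W"] = flat.T @ dyf
        grads[self.name + ".b"] = dyf.sum(axis=0)
        return (dyf @ params[self.name + ".W"].T).T.reshape(self.cin, h, w)


def _relu_fwd(x: np.ndarray, cache: dict, key: str) -> np.ndarray:
    mask = x > 0
    cache[key] = mask
    return x * mask


def _pool_fwd(x: np.ndarray, cache: dict, key: str) -> np.ndarray:
    c, h, w = x.shape
    xr = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    cache[key] = (idx, x.shape)
    return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]


def _pool_bwd(dy: np.ndarray, cache: dict, key: str) -> np.ndarray:
    idx, (c, h, w) = cache[key]
    dxr = np.zeros((c, h // 2, w // 2, 4))
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    return dxr.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h, w)


def _up_fwd(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _up_bwd(dy: np.ndarray) -> np.ndarray:
    c, h, w = dy.shape
    return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# the U-Net


@dataclass
class ModelState:
    """Architecture descriptor, parameter values, and training metadata."""

    depth: int
    base_channels: int
    params: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def model_id(self) -> str:
        return f"unet-d{self.depth}-c{self.base_channels}"

    def predict_probability_map(self, image: ImageGrid) -> ProbabilityMap:
        return predict_probability_map(self, image)


def _build_layers(depth: int, base: int) -> dict:
    enc = [_Conv3x3(f"enc{i}", 1 if i == 0 else base * 2 ** (i - 1), base * 2**i) for i in range(depth)]
    dec = []
    for i in range(depth - 2, -1, -1):
        ch = base * 2**i
        dec.append(
            (
                _Conv3x3(f"up{i}", ch * 2, ch),  # after nearest-neighbor upsample
                _Conv3x3(f"dec{i}", ch * 2, ch),  # after skip concatenation
            )
        )
    return {"enc": enc, "dec": dec, "head": _Conv1x1("head", base, 1)}


def _init_model(depth: int, base: int, seed: int) -> ModelState:
    if depth < 2:
        raise ValueError("depth must be >= 2")
    rng = np.random.default_rng(seed)
    layers = _build_layers(depth, base)
    params: dict = {}
    for conv in layers["enc"]:
        conv.init(rng, params)
    for up, dec in layers["dec"]:
        up.init(rng, params)
        dec.init(rng, params)
    layers["head"].init(rng, params)
    return ModelState(depth, base, params, {"seed": seed})


def _forward(
    model: ModelState, x2d: np.ndarray, cache: dict | None = None
) -> np.ndarray:
    """Logits for one (H, W) input; H and W must be multiples of 2^(depth-1)."""
    layers = _build_layers(model.depth, model.base_channels)
    params = model.params
    cache = cache if cache is not None else {}
    x = x2d[None]
    skips = []
    for i, conv in enumerate(layers["enc"]):
        x = _relu_fwd(conv.forward(x, params, cache), cache, f"relu_enc{i}")
        if i < model.depth - 1:
            skips.append(x)
            x = _pool_fwd(x, cache, f"pool{i}")
    for (up, dec), skip in zip(layers["dec"], reversed(skips)):
        x = _up_fwd(x)
        x = _relu_fwd(up.forward(x, params, cache), cache, f"relu_{up.name}")
        x = np.concatenate([skip, x], axis=0)
        x = _relu_fwd(dec.forward(x, params, cache), cache, f"relu_{dec.name}")
    logits = layers["head"].forward(x, params, cache)[0]
    cache["_layers"] = layers
    return logits


def _backward(model: ModelState, dlogits: np.ndarray, cache: dict) -> dict:
    layers = cache["_layers"]
    params = model.params
    grads: dict = {}
    dx = layers["head"].backward(dlogits[None], params, cache, grads)
    skip_grads = []  # indexed by encoder level 0..depth-2
    for up, dec in list(layers["dec"])[::-1]:
        dx = dx * cache[f"relu_{dec.name}"]
        dx = dec.backward(dx, params, cache, grads)
        half = dx.shape[0] // 2
        skip_grads.append(dx[:half])
        dx = dx[half:]
        dx = dx * cache[f"relu_{up.name}"]
        dx = up.backward(dx, params, cache, grads)
        dx = _up_bwd(dx)
    # encoder, deepest level first
    for i in range(model.depth - 1, -1, -1):
        if i < model.depth - 1:
            dx = _pool_bwd(dx, cache, f"pool{i}")
            dx = dx + skip_grads[i]
        dx = dx * cache[f"relu_enc{i}"]
        dx = layers["enc"][i].backward(dx, params, cache, grads)
    return grads


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (the architecture lives in ModelState)."""

    depth: int = 3
    base_channels: int = 16
    steps: int = 200
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


def train(
    pairs: list[TrainingPair],
    config: TrainConfig | None = None,
    seed: int = 0,
) -> ModelState:
    """Train the U-Net with Adam on BCE, cycling through the pairs.

    One gradient step per pair visit; all randomness (initialization) comes
    from ``seed``, so the loss trajectory is reproducible. Raises on a
    non-finite loss.
    """
    if not pairs:
        raise ValueError("at least one training pair is required")
    config = config or TrainConfig()
    factor = 2 ** (config.depth - 1)
    for p in pairs:
        if p.input.ndim != 2:
            raise ValueError("training pairs must be 2D")
        if any(s % factor for s in p.input.shape):
            raise ValueError(
                f"training pair shape {p.input.shape} must be a multiple of {factor}"
            )

    model = _init_model(config.depth, config.base_channels, seed)
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    history = []
    for step in range(config.steps):
        pair = pairs[step % len(pairs)]
        cache: dict = {}
        logits = _forward(model, pair.input, cache)
        prob = _sigmoid(logits)
        loss = bce_loss(prob, pair.label)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at step {step}")
        history.append(loss)
        dlogits = (prob - pair.label) / pair.label.size
        grads = _backward(model, dlogits, cache)
        t = step + 1
        b1, b2 = config.adam_beta1, config.adam_beta2
        for k, g in grads.items():
            m_state[k] = b1 * m_state[k] + (1 - b1) * g
            v_state[k] = b2 * v_state[k] + (1 - b2) * g * g
            mhat = m_state[k] / (1 - b1**t)
            vhat = v_state[k] / (1 - b2**t)
            model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + config.adam_eps)

    model.meta.update(
        {
            "seed": seed,
            "steps": config.steps,
            "learning_rate": config.learning_rate,
            "initial_loss": history[0],
            "final_loss": history[-1],
            "loss_history": history,
        }
    )
    return model


def _predict_slice(model: ModelState, data: np.ndarray) -> np.ndarray:
    factor = 2 ** (model.depth - 1)
    h, w = data.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        data = np.pad(data, ((0, ph), (0, pw)), mode="reflect")
    prob = _sigmoid(_forward(model, data))
    return prob[:h, :w]


def predict_probability_map(model: ModelState, image: ImageGrid) -> ProbabilityMap:
    """Probability map for a 2D image, or slice-wise along z for a volume.

    Inputs whose extent is not a multiple of the network's downsampling
    factor are reflect-padded and cropped back.
    """
    if image.ndim == 2:
        prob = _predict_slice(model, image.data)
    else:
        prob = np.stack([_predict_slice(model, sl) for sl in image.data])
    return ProbabilityMap(np.clip(prob, 0.0, 1.0), model.model_id)


def save_model(model: ModelState, path: str | Path) -> None:
    """Single-file checkpoint (.npz): parameters plus JSON metadata."""
    meta = {
        "format_version": 1,
        "depth": model.depth,
        "base_channels": model.base_channels,
        "meta": model.meta,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.params,
    )


def load_model(path: str | Path) -> ModelState:
    """Load a checkpoint; predictions after load are bit-identical."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        params = {k: archive[k].copy() for k in archive.files if k != "__meta__"}
    model = ModelState(meta["depth"], meta["base_channels"], params, meta.get("meta", {}))
    return model
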