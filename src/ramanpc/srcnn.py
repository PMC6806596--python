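"""Three-layer super-resolution CNN, implemented in plain numpy.

Layer shapes: 64 kernels of 9x9 on the gray input, 32 kernels of 5x5 on the
64 feature maps, and a single 5x5 reconstruction kernel. Hidden layers use
ReLU; every convolution pads by symmetric (reflect) boundary extension so
spatial dimensions are preserved. Inference normalizes pixels to [0, 1] and
the raw output is clipped to that range before rescaling to [0, 255].

Super-resolution alternates a bicubic x2 upscale with a network pass until
the image reaches the target size. Training is a small deterministic
Adam-on-MSE recipe on patch pairs; the network is warm-started at the
identity configuration (delta kernels plus small noise) so the untrained
network already reproduces its bicubic input and training only has to learn
the residual sharpening.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _sk_resize

__all__ = [
    "SRCNNWeights",
    "srcnn_forward",
    "srcnn_raw",
    "bicubic_upscale",
    "superresolve",
    "train_srcnn",
    "make_patch_pairs",
    "save_weights",
    "load_weights",
    "default_weights",
]

_SHAPES = {
    "w1": (64, 1, 9, 9), "b1": (64,),
    "w2": (32, 64, 5, 5), "b2": (32,),
    "w3": (1, 32, 5, 5), "b3": (1,),
}


@dataclass
class SRCNNWeights:
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray

    def __post_init__(self) -> None:
        for name, shape in _SHAPES.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    @classmethod
    def identity(cls) -> "SRCNNWeights":
        """Delta-kernel configuration: the network is the identity on [0,1]."""
        w1 = np.zeros(_SHAPES["w1"]); w1[0, 0, 4, 4] = 1.0
        w2 = np.zeros(_SHAPES["w2"]); w2[0, 0, 2, 2] = 1.0
        w3 = np.zeros(_SHAPES["w3"]); w3[0, 0, 2, 2] = 1.0
        return cls(w1=w1, b1=np.zeros(64), w2=w2, b2=np.zeros(32),
                   w3=w3, b3=np.zeros(1))

    @classmethod
    def near_identity(cls, rng: np.random.Generator, noise: float = 1e-4) -> "SRCNNWeights":
        w = cls.identity()
        for name in ("w1", "w2", "w3"):
            arr = getattr(w, name)
            setattr(w, name, arr + noise * rng.standard_normal(arr.shape))
        return w

    def params(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in _SHAPES}


def _conv(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Reflect-padded correlation. x: (B,C,H,W), w: (O,C,k,k) -> (B,O,H,W)."""
    r = w.shape[2] // 2
    xp = np.pad(x, ((0, 0), (0, 0), (r, r), (r, r)), mode="reflect")
    cols = sliding_window_view(xp, (w.shape[2], w.shape[3]), axis=(2, 3))
    out = np.tensordot(cols, w, axes=([1, 4, 5], [1, 2, 3]))  # (B,H,W,O)
    return np.moveaxis(out, 3, 1) + b[None, :, None, None]


def srcnn_raw(img01: np.ndarray, w: SRCNNWeights) -> np.ndarray:
    """Network output for a [0,1]-scaled image, before clipping."""
    img01 = np.asarray(img01, dtype=float)
    if img01.ndim != 2 or min(img01.shape) < 9:
        raise ValueError("input must be a 2-D image of at least 9x9")
    x = img01[None, None]
    f1 = np.maximum(_conv(x, w.w1, w.b1), 0.0)
    f2 = np.maximum(_conv(f1, w.w2, w.b2), 0.0)
    return _conv(f2, w.w3, w.b3)[0, 0]


def srcnn_forward(img: np.ndarray, w: SRCNNWeights) -> np.ndarray:
    """Restore a grayscale image in [0, 255]; dimensions are preserved."""
    out = srcnn_raw(np.asarray(img, dtype=float) / 255.0, w)
    return np.clip(out, 0.0, 1.0) * 255.0


def bicubic_upscale(img: np.ndarray, scale: int = 2) -> np.ndarray:
    """Deterministic bicubic upscale by an integer factor."""
    img = np.asarray(img, dtype=float)
    shape = (img.shape[0] * scale, img.shape[1] * scale)
    return np.asarray(
        _sk_resize(img, shape, order=3, mode="symmetric",
                   anti_aliasing=False, preserve_range=True),
        dtype=float,
    )


def superresolve(
    img: np.ndarray,
    w: SRCNNWeights | None = None,
    target_min: int = 320,
    scale: int = 2,
    use_network: bool = True,
) -> np.ndarray:
    """Repeat {bicubic x``scale``, network pass} until min side >= target."""
    img = np.asarray(img, dtype=float)
    if min(img.shape) < 10:
        raise ValueError("input must be at least 10x10")
    while min(img.shape) < target_min:
        img = bicubic_upscale(img, scale)
        if use_network:
            if w is None:
                w = default_weights()
            img = srcnn_forward(img, w)
    return img


# ---------------------------------------------------------------------------
# training


def _conv_backward(x, w, dy):
    """Gradients of _conv. Returns (dx, dw, db)."""
    k = w.shape[2]
    r = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (r, r), (r, r)), mode="reflect")
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
    dw = np.tensordot(dy, cols, axes=([0, 2, 3], [0, 2, 3]))  # (O,C,k,k)
    db = dy.sum(axis=(0, 2, 3))
    # full correlation of dy with flipped kernels -> gradient wrt padded input
    dyz = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
    wins = sliding_window_view(dyz, (k, k), axis=(2, 3))  # (B,O,H+2r,W+2r,k,k)
    wflip = w[:, :, ::-1, ::-1]
    dxp = np.tensordot(wins, wflip, axes=([1, 4, 5], [0, 2, 3]))  # (B,Hp,Wp,C)
    dxp = np.moveaxis(dxp, 3, 1)
    # adjoint of reflect padding: fold padded rows/cols back onto sources
    h, wd = x.shape[2], x.shape[3]
    ridx = np.pad(np.arange(h), r, mode="reflect")
    cidx = np.pad(np.arange(wd), r, mode="reflect")
    tmp = np.zeros((x.shape[0], x.shape[1], h, dxp.shape[3]))
    for a, i0 in enumerate(ridx):
        tmp[:, :, i0, :] += dxp[:, :, a, :]
    dx = np.zeros_like(x)
    for b_, j0 in enumerate(cidx):
        dx[:, :, :, j0] += tmp[:, :, :, b_]
    return dx, dw, db


def _loss_and_grads(x, t, w: SRCNNWeights):
    f1_pre = _conv(x, w.w1, w.b1)
    f1 = np.maximum(f1_pre, 0.0)
    f2_pre = _conv(f1, w.w2, w.b2)
    f2 = np.maximum(f2_pre, 0.0)
    y = _conv(f2, w.w3, w.b3)
    diff = y - t
    loss = float(np.mean(diff * diff))
    dy = (2.0 / diff.size) * diff
    df2, dw3, db3 = _conv_backward(f2, w.w3, dy)
    df2 *= f2_pre > 0
    df1, dw2, db2 = _conv_backward(f1, w.w2, df2)
    df1 *= f1_pre > 0
    _, dw1, db1 = _conv_backward(x, w.w1, df1)
    return loss, {"w1": dw1, "b1": db1, "w2": dw2, "b2": db2, "w3": dw3, "b3": db3}


def training_mse(pairs, w: SRCNNWeights) -> float:
    """Mean squared error of the network over (input, target) [0,1] pairs."""
    errs = [np.mean((srcnn_raw(x, w) - t) ** 2) for x, t in pairs]
    return float(np.mean(errs))


def train_srcnn(
    patches,
    seed: int = 0,
    epochs: int = 10,
    batch_size: int = 8,
    lr: float = 2e-4,
    scale: int = 2,
    callback=None,
) -> SRCNNWeights:
    """Fit the network on (low-res, high-res) grayscale patch pairs.

    Each low-res patch is bicubic-upscaled by ``scale`` to form the network
    input; the loss is the MSE against the high-res patch, both on the [0,1]
    scale. Fully deterministic for a fixed seed.
    """
    patches = list(patches)
    if not patches:
        raise ValueError("empty training set")
    xs, ts = [], []
    for low, high in patches:
        low = np.asarray(low, dtype=float)
        high = np.asarray(high, dtype=float)
        if min(high.shape) < 33:
            raise ValueError("high-res patches must be at least 33x33")
        up = bicubic_upscale(low, scale)
        if up.shape != high.shape:
            raise ValueError(
                f"bicubic x{scale} of {low.shape} gives {up.shape}, "
                f"target is {high.shape}"
            )
        xs.append(up / 255.0)
        ts.append(high / 255.0)
    x_all = np.stack(xs)[:, None]
    t_all = np.stack(ts)[:, None]

    rng = np.random.default_rng(seed)
    w = SRCNNWeights.near_identity(rng)
    mom = {n: np.zeros_like(p) for n, p in w.params().items()}
    vel = {n: np.zeros_like(p) for n, p in w.params().items()}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0
    n = x_all.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, grads = _loss_and_grads(x_all[idx], t_all[idx], w)
            step += 1
            for name, g in grads.items():
                mom[name] = beta1 * mom[name] + (1 - beta1) * g
                vel[name] = beta2 * vel[name] + (1 - beta2) * g * g
                m_hat = mom[name] / (1 - beta1**step)
                v_hat = vel[name] / (1 - beta2**step)
                p = getattr(w, name)
                setattr(w, name, p - lr * m_hat / (np.sqrt(v_hat) + adam_eps))
            if callback is not None:
                callback(step, loss)
    return w


def make_patch_pairs(images, patch: int = 34, stride: int = 14, scale: int = 2):
    """Cut (low, high) pairs from grayscale [0,255] images.

    High-res patches of ``patch`` pixels (must divide by ``scale``) are
    sampled on a stride grid; the low-res partner is a bicubic downscale by
    ``scale`` with anti-aliasing, emulating loss of detail.
    """
    if patch % scale != 0:
        raise ValueError("patch size must be divisible by the scale")
    pairs = []
    for img in images:
        img = np.asarray(img, dtype=float)
        for i in range(0, img.shape[0] - patch + 1, stride):
            for j in range(0, img.shape[1] - patch + 1, stride):
                high = img[i:i + patch, j:j + patch]
                low = _sk_resize(high, (patch // scale, patch // scale),
                                 order=3, mode="symmetric",
                                 anti_aliasing=True, preserve_range=True)
                pairs.append((np.asarray(low, dtype=float), high))
    return pairs


# ---------------------------------------------------------------------------
# weight (de)serialization


def save_weights(w: SRCNNWeights, path) -> None:
    """Write weights; ``.json`` gives a text container, anything else npz."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {n: p.tolist() for n, p in w.params().items()}
        path.write_text(json.dumps(payload))
    else:
        np.savez(path, **w.params())


def load_weights(path) -> SRCNNWeights:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        arrays = {n: np.asarray(v, dtype=float) for n, v in payload.items()}
    else:
        with np.load(path) as data:
            arrays = {n: data[n] for n in data.files}
    missing = set(_SHAPES) - set(arrays)
    if missing:
        raise ValueError(f"weight file {path} is missing arrays: {sorted(missing)}")
    return SRCNNWeights(**arrays)


_DEFAULT_WEIGHTS_PATH = Path(__file__).parent / "data" / "default_weights.json"
_default_cache: SRCNNWeights | None = None


def default_weights() -> SRCNNWeights:
    """Weights shipped with the package (see scripts/train_default_weights.py)."""
    global _default_cache
    if _default_cache is None:
        _default_cache = load_weights(_DEFAULT_WEIGHTS_PATH)
    return _default_cache
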