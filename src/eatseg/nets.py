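"""Multi-frame fully convolutional networks for 4-class cine segmentation.

Two architectures map a 3-frame cine window to a per-pixel probability map
over {background, EAT, PAT, HV} for the central frame:

* ``unet`` — encoder-decoder with skip connections: per level two 3×3
  convolutions (batch norm + ReLU) and 2×2 max-pooling; the decoder
  upsamples (bilinear + 3×3 conv), concatenates the skip connection and
  applies two more convolutions.
* ``fcnb`` — same encoder; the decoder simply upsamples every level's final
  feature map to the input resolution, concatenates them all, and fuses
  with two 3×3 convolutions.

Both start with a convolution over the (x, y, t) window whose temporal
extent equals the window length with valid padding, collapsing the three
input frames into one feature plane (for a temporal extent of 3 this is
algebraically a 2D convolution with one distinct 3×3 kernel per frame, which
is how it is computed here — the output genuinely depends on frame order).
Feature counts double per level (48 → 96 → 192 → 384 → 768 at the default
five levels) and a final 1×1 convolution + softmax produces 4 channels.

The networks are fully convolutional: any spatial size divisible by
``2**(n_levels-1)`` is accepted.  Everything (convolutions via im2col,
batch norm, pooling, bilinear upsampling, backpropagation) is implemented
directly on numpy arrays, with He-uniform seeded initialization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .dataio import MultiFrameSample


@dataclass
class NetworkConfig:
    first_layer_filters: int = 48
    n_levels: int = 5
    n_classes: int = 4
    temporal_extent: int = 3
    variant: str = "unet"
    conv_kernel: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("unet", "fcnb"):
            raise ValueError("variant must be 'unet' or 'fcnb'")
        if self.n_levels < 2:
            raise ValueError("need at least 2 levels")
        if self.temporal_extent != 3:
            raise ValueError("only 3-frame windows are supported")

    @property
    def level_features(self) -> list[int]:
        return [self.first_layer_filters * 2**l for l in range(self.n_levels)]


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2D:
    """k×k convolution with 'same' spatial padding, computed via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator, dtype=np.float32, name: str = ""):
        fan_in = c_in * k * k
        limit = np.sqrt(6.0 / fan_in)  # He-uniform for ReLU nets
        w = rng.uniform(-limit, limit, size=(c_out, fan_in)).astype(dtype)
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, (self.k - 1) // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k),
                                                        axis=(2, 3))
        if train:
            cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5))
            cols = cols.reshape(n * h * w, c * k * k)
            out = cols @ self.W.value.T + self.b.value
            self._cache = (cols, (n, c, h, w))
            return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)
        # inference: process in row blocks, never materialising the full
        # im2col matrix (wide concatenations would otherwise need GBs)
        self._cache = None
        block = max(1, int(2**27 // max(1, n * w * c * k * k)))
        out = np.empty((n, h, w, self.c_out), dtype=x.dtype)
        for r0 in range(0, h, block):
            r1 = min(h, r0 + block)
            chunk = np.ascontiguousarray(
                view[:, :, r0:r1].transpose(0, 2, 3, 1, 4, 5)
            ).reshape(n * (r1 - r0) * w, c * k * k)
            out[:, r0:r1] = (chunk @ self.W.value.T + self.b.value).reshape(
                n, r1 - r0, w, self.c_out)
        return out.transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        k, p = self.k, (self.k - 1) // 2
        g_mat = np.ascontiguousarray(g.transpose(0, 2, 3, 1))
        g_mat = g_mat.reshape(n * h * w, self.c_out)
        self.W.grad += g_mat.T @ cols
        self.b.grad += g_mat.sum(axis=0)
        gcols = (g_mat @ self.W.value).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += \
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm2D:
    def __init__(self, channels: int, dtype=np.float32, name: str = "",
                 momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c = x.shape[1]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
        self._cache = (xhat, inv_std, x.shape, train)
        return (self.gamma.value.reshape(1, c, 1, 1) * xhat
                + self.beta.value.reshape(1, c, 1, 1))

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape, train = self._cache
        n, c, h, w = shape
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))
        dxhat = g * self.gamma.value.reshape(1, c, 1, 1)
        if not train:
            self._cache = None
            return dxhat * inv_std.reshape(1, c, 1, 1)
        m = n * h * w
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - s1 / m - xhat * s2 / m) * inv_std.reshape(1, c, 1, 1)
        self._cache = None
        return dx

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._mask
        self._mask = None
        return out

    def params(self) -> list[Param]:
        return []


class MaxPool2:
    """2×2 max pooling with stride 2."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, c, h, w))
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return gr.reshape(n, c, h, w)

    def params(self) -> list[Param]:
        return []


def _up1d(x: np.ndarray, axis: int) -> np.ndarray:
    """Factor-2 bilinear upsampling (half-pixel centers) along one axis."""
    x = np.moveaxis(x, axis, -1)
    prev = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    nxt = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    y = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
    y[..., 0::2] = 0.75 * x + 0.25 * prev
    y[..., 1::2] = 0.75 * x + 0.25 * nxt
    return np.moveaxis(y, -1, axis)


def _up1d_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    dx = 0.75 * (ge + go)
    dx[..., :-1] += 0.25 * ge[..., 1:]
    dx[..., 0] += 0.25 * ge[..., 0]
    dx[..., 1:] += 0.25 * go[..., :-1]
    dx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(dx, -1, axis)


class Upsample2:
    """Factor-2 bilinear upsampling over the two spatial axes."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return _up1d(_up1d(x, 2), 3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return _up1d_adjoint(_up1d_adjoint(g, 3), 2)

    def params(self) -> list[Param]:
        return []


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


def _conv_block(c_in: int, c_out: int, k: int, rng, dtype, name: str
                ) -> Sequential:
    return Sequential(
        Conv2D(c_in, c_out, k, rng, dtype, name),
        BatchNorm2D(c_out, dtype, name),
        ReLU(),
    )


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the networks
# ---------------------------------------------------------------------------

class MultiFrameNet:
    """Shared encoder + variant-specific decoder; see module docstring."""

    def __init__(self, config: NetworkConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 0x1247])
        )
        f = config.level_features
        L = config.n_levels
        k = config.conv_kernel

        # encoder: level 0 starts with the temporal (3-frame) convolution
        self.enc: list[Sequential] = []
        self.pools: list[MaxPool2] = []
        for l in range(L):
            c_in = config.temporal_extent if l == 0 else f[l - 1]
            self.enc.append(Sequential(
                *_conv_block(c_in, f[l], k, rng, dtype,
                             f"enc{l}a" + ("_temporal" if l == 0 else "")
                             ).layers,
                *_conv_block(f[l], f[l], k, rng, dtype, f"enc{l}b").layers,
            ))
            if l > 0:
                self.pools.append(MaxPool2())

        if config.variant == "unet":
            self.up: dict[int, Upsample2] = {}
            self.upconv: dict[int, Sequential] = {}
            self.dec: dict[int, Sequential] = {}
            for l in range(L - 1, 0, -1):
                self.up[l] = Upsample2()
                self.upconv[l] = _conv_block(f[l], f[l - 1], k, rng, dtype,
                                             f"up{l}")
                self.dec[l] = Sequential(
                    *_conv_block(2 * f[l - 1], f[l - 1], k, rng, dtype,
                                 f"dec{l}a").layers,
                    *_conv_block(f[l - 1], f[l - 1], k, rng, dtype,
                                 f"dec{l}b").layers,
                )
            head_in = f[0]
        else:  # fcnb
            self.fcnb_ups: list[list[Upsample2]] = [
                [Upsample2() for _ in range(l)] for l in range(L)
            ]
            self.fusion = Sequential(
                *_conv_block(sum(f), f[0], k, rng, dtype, "fusion_a").layers,
                *_conv_block(f[0], f[0], k, rng, dtype, "fusion_b").layers,
            )
            head_in = f[0]
        self.head = Conv2D(head_in, config.n_classes, 1, rng, dtype, "head")
        # background-prior initialization: the dice loss carries no explicit
        # background term, so start with background dominant everywhere;
        # otherwise a foreground class can flood the background early and
        # receive almost no corrective gradient
        self.head.b.value[0] = 2.0
        self._cache = None

    # -- plumbing ----------------------------------------------------------

    def _check_grid(self, h: int, w: int) -> None:
        div = 2 ** (self.config.n_levels - 1)
        if h % div or w % div:
            raise ValueError(
                f"spatial size {h}x{w} is not divisible by {div} "
                f"(= 2**(n_levels-1)); fit the input to a compatible grid "
                "first (see dataio.fit_to_grid)"
            )

    def params(self) -> list[Param]:
        out = []
        for block in self.enc:
            out.extend(block.params())
        out.extend(self._decoder_params())
        out.extend(self.head.params())
        return out

    def _decoder_params(self) -> list[Param]:
        out = []
        if self.config.variant == "unet":
            for l in sorted(self.upconv):
                out.extend(self.upconv[l].params())
                out.extend(self.dec[l].params())
        else:
            out.extend(self.fusion.params())
        return out

    def parameter_counts(self) -> dict[str, int]:
        enc = sum(p.value.size for b in self.enc for p in b.params())
        dec = sum(p.value.size for p in self._decoder_params())
        dec += sum(p.value.size for p in self.head.params())
        return {"encoder": int(enc), "decoder": int(dec),
                "total": int(enc + dec)}

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 3, H, W) window batch → (N, 4, H, W) probability maps."""
        if x.ndim != 4 or x.shape[1] != self.config.temporal_extent:
            raise ValueError(
                f"expected (N, {self.config.temporal_extent}, H, W) input, "
                f"got {x.shape}"
            )
        self._check_grid(x.shape[2], x.shape[3])
        x = np.ascontiguousarray(x, dtype=self.dtype)
        L = self.config.n_levels

        feats = []
        h = x
        for l in range(L):
            if l > 0:
                h = self.pools[l - 1].forward(h, train)
            h = self.enc[l].forward(h, train)
            feats.append(h)

        if self.config.variant == "unet":
            h = feats[-1]
            for l in range(L - 1, 0, -1):
                h = self.up[l].forward(h, train)
                h = self.upconv[l].forward(h, train)
                h = np.concatenate([h, feats[l - 1]], axis=1)
                h = self.dec[l].forward(h, train)
            logits = self.head.forward(h, train)
        else:
            ups = []
            for l in range(L):
                u = feats[l]
                for up in self.fcnb_ups[l]:
                    u = up.forward(u, train)
                ups.append(u)
            h = np.concatenate(ups, axis=1)
            h = self.fusion.forward(h, train)
            logits = self.head.forward(h, train)

        probs = softmax_channels(logits.astype(np.float64)).astype(self.dtype)
        self._cache = probs
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the probability maps."""
        probs = self._cache
        if probs is None:
            raise RuntimeError("forward must be called before backward")
        # softmax jacobian: dz = p * (dp - sum_c dp*p)
        inner = (dprobs * probs).sum(axis=1, keepdims=True)
        g = (probs * (dprobs - inner)).astype(self.dtype)
        L = self.config.n_levels
        f = self.config.level_features

        g = self.head.backward(g)
        skip_grads: list[np.ndarray | None] = [None] * L
        if self.config.variant == "unet":
            for l in range(1, L):
                g = self.dec[l].backward(g)
                g_up, g_skip = g[:, :f[l - 1]], g[:, f[l - 1]:]
                skip_grads[l - 1] = np.ascontiguousarray(g_skip)
                g = self.upconv[l].backward(np.ascontiguousarray(g_up))
                g = self.up[l].backward(g)
            skip_grads[L - 1] = g
        else:
            g = self.fusion.backward(g)
            start = 0
            for l in range(L):
                u = np.ascontiguousarray(g[:, start:start + f[l]])
                start += f[l]
                for up in reversed(self.fcnb_ups[l]):
                    u = up.backward(u)
                skip_grads[l] = u

        g = skip_grads[L - 1]
        for l in range(L - 1, -1, -1):
            g = self.enc[l].backward(g)
            if l > 0:
                g = self.pools[l - 1].backward(g)
                g = g + skip_grads[l - 1]
        self._cache = None

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.params()):
            state[f"{i:04d}:{p.name}"] = p.value
        # batch-norm running statistics
        for j, bn in enumerate(self._batchnorms()):
            state[f"bn{j:04d}:mean"] = bn.running_mean
            state[f"bn{j:04d}:var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.array(state[f"{i:04d}:{p.name}"], dtype=self.dtype)
            p.grad = np.zeros_like(p.value)
        for j, bn in enumerate(self._batchnorms()):
            bn.running_mean = np.array(state[f"bn{j:04d}:mean"],
                                       dtype=self.dtype)
            bn.running_var = np.array(state[f"bn{j:04d}:var"],
                                      dtype=self.dtype)

    def _batchnorms(self) -> list[BatchNorm2D]:
        bns = []
        for block in self.enc:
            bns.extend(l for l in block.layers if isinstance(l, BatchNorm2D))
        if self.config.variant == "unet":
            for l in sorted(self.upconv):
                bns.extend(x for x in self.upconv[l].layers
                           if isinstance(x, BatchNorm2D))
                bns.extend(x for x in self.dec[l].layers
                           if isinstance(x, BatchNorm2D))
        else:
            bns.extend(x for x in self.fusion.layers
                       if isinstance(x, BatchNorm2D))
        return bns


def build_network(config: NetworkConfig, dtype=np.float32) -> MultiFrameNet:
    """Construct a seeded, He-uniform-initialized network."""
    return MultiFrameNet(config, dtype=dtype)


def predict_frame(
    network: MultiFrameNet, sample: MultiFrameSample
) -> tuple[np.ndarray, np.ndarray]:
    """Run inference on one sample.

    Returns ``(probability_map, label_map)`` where the label map is the
    per-pixel argmax over the 4 classes; exact ties resolve to the lower
    class index (background first), deterministically.
    """
    x = sample.window[None].astype(network.dtype)
    probs = network.forward(x, train=False)[0]
    labels = np.argmax(probs, axis=0).astype(np.int16)
    return probs, labels


def save_checkpoint(network: MultiFrameNet, path: str | Path,
                    extra: dict | None = None) -> None:
    """Save weights as .npz with a JSON sidecar recording the config."""
    path = Path(path)
    np.savez(path, **network.state_dict())
    sidecar = {"network_config": asdict(network.config)}
    if extra:
        sidecar.update(extra)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path: str | Path, dtype=np.float32) -> MultiFrameNet:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    config = NetworkConfig(**sidecar["network_config"])
    net = MultiFrameNet(config, dtype=dtype)
    with np.load(path if path.suffix == ".npz"
                 else path.with_suffix(".npz")) as data:
        net.load_state_dict(dict(data))
    return net
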