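"""Neural-network layers on the autodiff engine.

Contains exactly what the reconstruction needs: dense layers / MLPs for the
coordinate networks, and a small 2D U-Net (3x3 convs, instance norm, ReLU,
average-pool downsampling, nearest-neighbor upsampling) used as the learned
proximal operator, plus LoRA-wrapped convolutions for rapid adaptation.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, custom_op

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "Conv2d",
    "LoRAConv2d",
    "InstanceNorm2d",
    "UNet",
    "conv2d",
    "avg_pool2d",
    "upsample_nearest2d",
]


class Module:
    """Minimal container with named-parameter discovery and freezing."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Tensor) and getattr(value, "_is_param", False):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self):
        return [p for p in self.parameters() if p.requires_grad]

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True
        return self

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def n_trainable(self) -> int:
        return int(sum(p.size for p in self.trainable_parameters()))

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        for name, arr in state.items():
            if name not in own:
                raise KeyError(f"unknown parameter {name!r}")
            if own[name].data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            own[name].data = np.array(arr, dtype=own[name].data.dtype, copy=True)
        return self


# Tensor is __slots__-based; the subclass adds the parameter marker slot
class _PTensor(Tensor):
    __slots__ = ("_is_param",)


def _param(data, dtype=np.float32) -> Tensor:
    t = _PTensor(np.asarray(data, dtype=dtype), requires_grad=True)
    t._is_param = True
    return t


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = _param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = _param(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Fully connected network with ReLU hidden activations."""

    def __init__(self, n_in, hidden, n_out, rng):
        sizes = [n_in] + list(hidden) + [n_out]
        self.layers = [
            Linear(sizes[i], sizes[i + 1], rng) for i in range(len(sizes) - 1)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, pad: int = 1) -> Tensor:
    """Stride-1 2D convolution with zero padding, channels-last layout.

    ``x``: (B, H, W, Cin); ``weight``: (Cout, Cin, kh, kw); ``bias``:
    (Cout,).  Implemented as one GEMM per kernel offset (shift-and-multiply)
    which avoids im2col copies at these channel counts.
    """
    cout, cin, kh, kw = weight.shape
    xd = x.data
    if xd.shape[3] != cin:
        raise ValueError(f"channel mismatch: input {xd.shape[3]} vs weight {cin}")
    b, h, w = xd.shape[:3]
    xp = (
        np.pad(xd, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else xd
    )
    # weight as (kh, kw, Cin, Cout) slabs
    wk = np.ascontiguousarray(weight.data.transpose(2, 3, 1, 0))
    out = np.zeros((b * h * w, cout), dtype=xd.dtype)
    xs_list = []
    for i in range(kh):
        for j in range(kw):
            xs = np.ascontiguousarray(
                xp[:, i : i + h, j : j + w, :]
            ).reshape(b * h * w, cin)
            xs_list.append(xs)
            out += xs @ wk[i, j]
    if bias is not None:
        out += bias.data
    out = out.reshape(b, h, w, cout)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = np.ascontiguousarray(g).reshape(b * h * w, cout)
        gw = np.empty_like(weight.data)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                xs = xs_list[i * kw + j]
                gw[:, :, i, j] = (xs.T @ gmat).T
                gxs = gmat @ wk[i, j].T
                gxp[:, i : i + h, j : j + w, :] += gxs.reshape(b, h, w, cin)
        gx = gxp[:, pad : pad + h, pad : pad + w, :] if pad else gxp
        if bias is None:
            return gx, gw
        return gx, gw, gmat.sum(axis=0)

    return custom_op(out, parents, backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    b, h, w, c = x.shape
    if h % k or w % k:
        raise ValueError("spatial size must be divisible by the pool factor")
    return x.reshape(b, h // k, k, w // k, k, c).mean(axis=(2, 4))


def upsample_nearest2d(x: Tensor, k: int = 2) -> Tensor:
    b, h, w, c = x.shape
    out = np.repeat(np.repeat(x.data, k, axis=1), k, axis=2)

    def backward(g):
        return (g.reshape(b, h, k, w, k, c).sum(axis=(2, 4)),)

    return custom_op(out, (x,), backward)


class Conv2d(Module):
    def __init__(self, cin, cout, rng, kernel=3, bias=True):
        scale = np.sqrt(2.0 / (cin * kernel * kernel))
        self.weight = _param(rng.normal(0.0, scale, size=(cout, cin, kernel, kernel)))
        self.bias = _param(np.zeros(cout)) if bias else None
        self.pad = kernel // 2

    def effective_weight(self) -> Tensor:
        return self.weight

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.effective_weight(), self.bias, pad=self.pad)


class LoRAConv2d(Module):
    """Convolution with a frozen base weight plus a trainable low-rank update.

    The effective kernel is ``W0 + β · (A B)`` with ``A (m×r)`` drawn from a
    scaled normal and ``B (r×l)`` zero-initialized, so wrapping is exactly
    the identity until training starts.  ``m`` is the output-channel count
    and ``l = cin·kh·kw``.
    """

    def __init__(self, base: Conv2d, rank: int, beta: float, rng):
        w = base.weight
        cout, cin, kh, kw = w.shape
        m, l = cout, cin * kh * kw
        if rank >= min(m, l):
            raise ValueError(f"LoRA rank {rank} must be < min(m, l) = {min(m, l)}")
        w.requires_grad = False
        self.base_weight = w
        self.bias = base.bias
        if self.bias is not None:
            self.bias.requires_grad = False
        self.lora_a = _param(rng.normal(0.0, 1.0 / np.sqrt(rank), size=(m, rank)))
        self.lora_b = _param(np.zeros((rank, l)))
        self.beta = float(beta)
        self.pad = base.pad
        self._kshape = (cout, cin, kh, kw)

    def effective_weight(self) -> Tensor:
        delta = (self.lora_a @ self.lora_b).reshape(*self._kshape) * self.beta
        return self.base_weight + delta

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.effective_weight(), self.bias, pad=self.pad)

    def merged_weight(self) -> np.ndarray:
        """Base plus low-rank update, flattened into a plain kernel."""
        return self.effective_weight().data.copy()


class InstanceNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))
        self.eps = eps
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        m = x.mean(axis=(1, 2), keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=(1, 2), keepdims=True)
        xn = xc / (v + self.eps).sqrt()
        c = self.channels
        return xn * self.gamma.reshape(1, 1, 1, c) + self.beta.reshape(1, 1, 1, c)


class _ConvBlock(Module):
    def __init__(self, cin, cout, rng):
        self.conv1 = Conv2d(cin, cout, rng)
        self.norm1 = InstanceNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, rng)
        self.norm2 = InstanceNorm2d(cout)

    def __call__(self, x):
        x = self.norm1(self.conv1(x)).relu()
        return self.norm2(self.conv2(x)).relu()


class UNet(Module):
    """2D encoder-decoder with skip connections, channels-last (B, H, W, C).

    ``depth`` resolution levels with channel widths ``base · 2^level``; the
    input spatial size must be divisible by ``2^(depth-1)``.
    """

    def __init__(
        self,
        in_channels=4,
        out_channels=4,
        base=32,
        depth=4,
        rng=None,
        zero_init_output=True,
    ):
        rng = np.random.default_rng(0) if rng is None else rng
        widths = [base * 2**i for i in range(depth)]
        self.enc = []
        cin = in_channels
        for wdt in widths:
            self.enc.append(_ConvBlock(cin, wdt, rng))
            cin = wdt
        self.dec = []
        for i in range(depth - 2, -1, -1):
            self.dec.append(_ConvBlock(widths[i + 1] + widths[i], widths[i], rng))
        self.out_conv = Conv2d(widths[0], out_channels, rng, kernel=1)
        if zero_init_output:
            # the network starts as the zero map, so a residual proximal
            # operator is exactly the identity until training moves it
            self.out_conv.weight.data[...] = 0.0
            self.out_conv.bias.data[...] = 0.0
        self.depth = depth

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        for i, block in enumerate(self.enc):
            x = block(x)
            if i < self.depth - 1:
                skips.append(x)
                x = avg_pool2d(x, 2)
        for block, skip in zip(self.dec, reversed(skips)):
            x = upsample_nearest2d(x, 2)
            x = block(concat([x, skip], axis=3))
        return self.out_conv(x)

    def conv_modules(self):
        """All convolution submodules, in a stable order."""
        mods = []

        def collect(m):
            for v in vars(m).values():
                if isinstance(v, (Conv2d, LoRAConv2d)):
                    mods.append(v)
                elif isinstance(v, Module):
                    collect(v)
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, (Conv2d, LoRAConv2d)):
                            mods.append(item)
                        elif isinstance(item, Module):
                            collect(item)

        collect(self)
        return mods
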