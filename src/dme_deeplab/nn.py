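"""Minimal CPU neural-network layers with manual backpropagation.

The segmentation model needs only a handful of primitives: dense and
depthwise 2-D convolutions (with stride and dilation), batch normalization,
bounded rectifiers, bilinear resizing, channel concatenation and residual
addition, pixel-wise softmax cross-entropy and SGD with momentum.  They are
implemented here directly on numpy arrays in NCHW layout, each module caching
what its backward pass needs.

Convolutions are evaluated as a sum over the k*k kernel taps: for each tap a
strided slice of the (zero-padded) input is contracted with the corresponding
weight plane by a batched matmul.  This keeps both passes allocation-light and
fully vectorized over batch and space, which is what makes CPU training of the
compact model practical.  Everything is deterministic given the seed passed to
the initializer; no threading or global RNG state is used.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32  # training precision; float32 halves memory traffic on CPU

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU6",
    "ReLU",
    "Identity",
    "BilinearResize",
    "softmax_cross_entropy",
    "SGD",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray) -> None:
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: tracks parameters, buffers (running stats) and submodules."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    # -- registration ------------------------------------------------------
    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for k, p in self._params.items():
            state[prefix + k] = p.data
        for k, b in self._buffers.items():
            state[prefix + k] = b
        for name, m in self._modules.items():
            state.update(m.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, p in self._params.items():
            src = state[prefix + k]
            if src.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {prefix + k}: "
                    f"checkpoint {src.shape} vs model {p.data.shape}"
                )
            p.data[...] = src
        for k in self._buffers:
            self._buffers[k][...] = state[prefix + k]
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- interface ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            self.add_module(str(i), layer)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_out: int) -> np.ndarray:
    # He normal, fan-out mode: keeps activation variance stable under ReLU.
    std = np.sqrt(2.0 / fan_out)
    return rng.normal(0.0, std, size=shape)


def _conv_geometry(h: int, w: int, k: int, stride: int, dilation: int) -> tuple[int, int, int]:
    """Same-style padding: output side = ceil(side / stride) for odd k."""
    pad = dilation * (k - 1) // 2
    eff = dilation * (k - 1) + 1
    ho = (h + 2 * pad - eff) // stride + 1
    wo = (w + 2 * pad - eff) // stride + 1
    return pad, ho, wo


class Conv2d(Module):
    """Dense 2-D convolution, NCHW, 'same' padding, optional stride/dilation."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = k
        self.stride = stride
        self.dilation = dilation
        fan_out = k * k * out_channels
        self.weight = Parameter(he_init(rng, (out_channels, in_channels, k, k), fan_out))
        self._params["weight"] = self.weight
        self.bias = None
        if bias:
            self.bias = Parameter(np.zeros(out_channels))
            self._params["bias"] = self.bias
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k, s, d = self.k, self.stride, self.dilation
        pad, ho, wo = _conv_geometry(h, w, k, s, d)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        out = np.zeros((n, self.out_channels, ho * wo), dtype=x.dtype)
        wflat = self.weight.data  # (O, C, k, k)
        slices = []
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i * d : i * d + s * (ho - 1) + 1 : s,
                            j * d : j * d + s * (wo - 1) + 1 : s]
                xs2 = np.ascontiguousarray(xs).reshape(n, c, ho * wo)
                out += np.matmul(wflat[:, :, i, j], xs2)
                slices.append(xs2)
        out = out.reshape(n, self.out_channels, ho, wo)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (x.shape, xp.shape, pad, ho, wo, slices)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (xshape, xpshape, pad, ho, wo, slices) = self._cache
        n, c, h, w = xshape
        k, s, d = self.k, self.stride, self.dilation
        g2 = grad.reshape(n, self.out_channels, ho * wo)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=(0, 2))
        gxp = np.zeros(xpshape, dtype=grad.dtype)
        wdata = self.weight.data
        idx = 0
        for i in range(k):
            for j in range(k):
                xs2 = slices[idx]
                idx += 1
                # dW: contract over batch and space
                self.weight.grad[:, :, i, j] += np.tensordot(g2, xs2, axes=([0, 2], [0, 2]))
                # dX: scatter back through the same strided slice
                gx2 = np.matmul(wdata[:, :, i, j].T, g2)
                gxp[:, :, i * d : i * d + s * (ho - 1) + 1 : s,
                        j * d : j * d + s * (wo - 1) + 1 : s] += gx2.reshape(n, c, ho, wo)
        if pad:
            return gxp[:, :, pad:-pad, pad:-pad]
        return gxp


class DepthwiseConv2d(Module):
    """Per-channel 3x3 (or kxk) convolution; parameters = k*k per channel."""

    def __init__(
        self,
        channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.k = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.weight = Parameter(he_init(rng, (channels, kernel_size, kernel_size),
                                        kernel_size * kernel_size))
        self._params["weight"] = self.weight
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        k, s, d = self.k, self.stride, self.dilation
        pad, ho, wo = _conv_geometry(h, w, k, s, d)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        out = np.zeros((n, c, ho, wo), dtype=x.dtype)
        slices = []
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i * d : i * d + s * (ho - 1) + 1 : s,
                            j * d : j * d + s * (wo - 1) + 1 : s]
                out += self.weight.data[None, :, i, j, None, None] * xs
                slices.append(xs)
        self._cache = (xp.shape, pad, ho, wo, slices)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xpshape, pad, ho, wo, slices = self._cache
        n, c = xpshape[0], xpshape[1]
        k, s, d = self.k, self.stride, self.dilation
        gxp = np.zeros(xpshape, dtype=grad.dtype)
        idx = 0
        for i in range(k):
            for j in range(k):
                xs = slices[idx]
                idx += 1
                self.weight.grad[:, i, j] += np.einsum("nchw,nchw->c", grad, xs)
                gxp[:, :, i * d : i * d + s * (ho - 1) + 1 : s,
                        j * d : j * d + s * (wo - 1) + 1 : s] += (
                    self.weight.data[None, :, i, j, None, None] * grad)
        if pad:
            return gxp[:, :, pad:-pad, pad:-pad]
        return gxp


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._params["gamma"] = self.gamma
        self._params["beta"] = self.beta
        self._buffers["running_mean"] = np.zeros(channels, dtype=DTYPE)
        self._buffers["running_var"] = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm += self.momentum * (mean - rm)
            rv += self.momentum * (var - rv)
        else:
            mean = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        self.gamma.grad += np.einsum("nchw,nchw->c", grad, xhat)
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None] / std[None, :, None, None]
        if not self.training:
            return g * grad
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        gmean = grad.mean(axis=(0, 2, 3))[None, :, None, None]
        gxhat_mean = np.einsum("nchw,nchw->c", grad, xhat)[None, :, None, None] / m
        return g * (grad - gmean - xhat * gxhat_mean)


class ReLU6(Module):
    """Bounded rectifier min(max(x, 0), 6) — the MobileNetV2 nonlinearity."""

    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = (x > 0) & (x < 6.0)
        return np.clip(x, 0.0, 6.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Identity(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) interpolation matrix, half-pixel centers."""
    mat = np.zeros((n_out, n_in), dtype=DTYPE)
    if n_in == 1:
        mat[:, 0] = 1.0
        return mat
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    mat[np.arange(n_out), lo] += 1.0 - frac
    mat[np.arange(n_out), hi] += frac
    return mat


class BilinearResize(Module):
    """Deterministic bilinear resize to a fixed output size (half-pixel convention).

    Implemented as two separable linear maps, so the backward pass is exactly
    the transpose — no atomics, no sampling ambiguity.
    """

    def __init__(self, out_h: int, out_w: int) -> None:
        super().__init__()
        self.out_h = out_h
        self.out_w = out_w
        self._mats: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._in_hw = None

    def _get_mats(self, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
        key = (h, w)
        if key not in self._mats:
            self._mats[key] = (_bilinear_matrix(h, self.out_h),
                               _bilinear_matrix(w, self.out_w))
        return self._mats[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        self._in_hw = (h, w)
        ah, aw = self._get_mats(h, w)
        y = np.matmul(x, aw.T)          # (N, C, H, Wo)
        return np.matmul(ah, y)         # (N, C, Ho, Wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        ah, aw = self._get_mats(*self._in_hw)
        g = np.matmul(ah.T, grad)
        return np.matmul(g, aw)


def softmax_cross_entropy(
    logits: np.ndarray,
    targets: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Mean pixel-wise cross-entropy and its gradient w.r.t. the logits.

    ``logits``: (N, C, H, W); ``targets``: (N, H, W) integer labels.
    With ``class_weights`` the loss is the weighted mean over pixels.
    """
    n, c, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    t = targets.astype(int)
    pix = np.take_along_axis(p, t[:, None, :, :], axis=1)[:, 0]
    nll = -np.log(np.maximum(pix, 1e-12))
    if class_weights is None:
        loss = float(nll.mean())
        grad = p.copy()
        np.put_along_axis(grad, t[:, None, :, :], (pix - 1.0)[:, None], axis=1)
        grad /= n * h * w
    else:
        wmap = class_weights[t]
        wsum = wmap.sum()
        loss = float((wmap * nll).sum() / wsum)
        grad = p.copy()
        np.put_along_axis(grad, t[:, None, :, :], (pix - 1.0)[:, None], axis=1)
        grad *= wmap[:, None, :, :] / wsum
    return loss, grad


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
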