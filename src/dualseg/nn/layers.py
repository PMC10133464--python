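"""Neural-network layers on top of the autodiff tensor.

All spatial layers are rank-agnostic (2D or 3D); convolution uses an
im2col/col2im pair, pooling and upsampling use exact reshape tricks so the
stride-2 geometry stays bit-clean.
"""
from __future__ import annotations

from math import prod

import numpy as np

from .tensor import Tensor, _accum, _make, astensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight module container: parameter discovery, modes, state."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def requires_grad_(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            for bname, buf in getattr(m, "_buffers", {}).items():
                state[f"__buf{i}.{bname}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.array(state[name])
        for i, m in enumerate(self.modules()):
            for bname in getattr(m, "_buffers", {}):
                m._buffers[bname] = np.array(state[f"__buf{i}.{bname}"])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# -- convolution -------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int, rank: int,
            out_sp: tuple[int, ...]) -> np.ndarray:
    """[N, C, *padded] -> [C*k^rank, N*L] patch matrix (single copy)."""
    n, c = xp.shape[:2]
    win = np.lib.stride_tricks.sliding_window_view(
        xp, (k,) * rank, axis=tuple(range(2, 2 + rank)))
    idx = (slice(None), slice(None)) + (slice(None, None, stride),) * rank
    win = win[idx]  # [N, C, *out_sp, *k^rank]
    perm = (1,) + tuple(range(2 + rank, 2 + 2 * rank)) + (0,) + tuple(range(2, 2 + rank))
    win = np.ascontiguousarray(np.transpose(win, perm))
    return win.reshape(c * k ** rank, n * prod(out_sp))


def _col2im(dcols: np.ndarray, in_shape: tuple, k: int, stride: int,
            rank: int, pad: int, out_sp: tuple[int, ...]) -> np.ndarray:
    """Scatter-add patch gradients [C*k^rank, N*L] back to the unpadded input."""
    n, c = in_shape[:2]
    padded = tuple(s + 2 * pad for s in in_shape[2:])
    dxp = np.zeros((c, n) + padded)
    kk = k ** rank
    d = dcols.reshape((c, kk, n) + out_sp)
    for t in range(kk):
        offs = np.unravel_index(t, (k,) * rank)
        sl = tuple(slice(o, o + stride * s, stride) for o, s in zip(offs, out_sp))
        dxp[(slice(None), slice(None)) + sl] += d[:, t]
    if pad:
        core = tuple(slice(pad, pad + s) for s in in_shape[2:])
        dxp = dxp[(slice(None), slice(None)) + core]
    return np.ascontiguousarray(dxp.swapaxes(0, 1))


class ConvNd(Module):
    def __init__(self, rank: int, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, pad: int = 0, bias: bool = True):
        super().__init__()
        self.rank, self.in_ch, self.out_ch = rank, in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.weight = Parameter(np.zeros((out_ch, in_ch) + (kernel,) * rank))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        x = astensor(x)
        rank, k, stride, pad = self.rank, self.kernel, self.stride, self.pad
        xd = x.data
        if xd.ndim != 2 + rank:
            raise ValueError(f"expected {2 + rank}D input, got shape {xd.shape}")
        if pad:
            xp = np.zeros(xd.shape[:2] + tuple(s + 2 * pad for s in xd.shape[2:]))
            xp[(slice(None), slice(None))
               + tuple(slice(pad, pad + s) for s in xd.shape[2:])] = xd
        else:
            xp = xd
        out_sp = tuple((s - k) // stride + 1 for s in xp.shape[2:])
        if any(s < 1 for s in out_sp):
            raise ValueError(f"input spatial shape {xd.shape[2:]} too small for "
                             f"kernel {k} stride {stride} pad {pad}")
        n = xd.shape[0]
        length = 1
        for s in out_sp:
            length *= s
        cols = _im2col(xp, k, stride, rank, out_sp)  # [C*k^r, N*L]
        w2 = self.weight.data.reshape(self.out_ch, -1)
        out = w2 @ cols  # [out_ch, N*L]
        if self.bias is not None:
            out = out + self.bias.data[:, None]
        out = np.ascontiguousarray(
            out.reshape((self.out_ch, n) + out_sp).swapaxes(0, 1))
        weight, bias = self.weight, self.bias
        in_shape = xd.shape

        def bwd(g):
            g2 = np.ascontiguousarray(g.swapaxes(0, 1)).reshape(self.out_ch, -1)
            _accum(weight, (g2 @ cols.T).reshape(weight.data.shape))
            if bias is not None:
                _accum(bias, g2.sum(axis=1))
            if x.requires_grad or x._backward is not None:
                dcols = w2.T @ g2
                _accum(x, _col2im(dcols, in_shape, k, stride, rank, pad, out_sp))

        parents = (x, weight) + ((bias,) if bias is not None else ())
        return _make(out, parents, bwd)


class MaxPoolNd(Module):
    """Non-overlapping 2x window max pooling; dims must be even."""

    def __init__(self, rank: int):
        super().__init__()
        self.rank = rank

    def forward(self, x: Tensor) -> Tensor:
        x = astensor(x)
        xd = x.data
        rank = self.rank
        if any(s % 2 for s in xd.shape[2:]):
            raise ValueError(f"odd spatial dims {xd.shape[2:]} cannot be 2x-pooled")
        n, c = xd.shape[:2]
        out_sp = tuple(s // 2 for s in xd.shape[2:])
        shape = (n, c) + sum(((s, 2) for s in out_sp), ())
        xr = xd.reshape(shape)
        # move the window axes (3, 5, ...) to the end
        win_axes = tuple(3 + 2 * i for i in range(rank))
        keep_axes = (0, 1) + tuple(2 + 2 * i for i in range(rank))
        xr = np.transpose(xr, keep_axes + win_axes).reshape(
            (n, c) + out_sp + (2 ** rank,))
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            dxr = np.zeros(xr.shape)
            np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
            dxr = dxr.reshape((n, c) + out_sp + (2,) * rank)
            inv = np.argsort(keep_axes + win_axes)
            _accum(x, np.transpose(dxr, inv).reshape(xd.shape))

        return _make(out, (x,), bwd)


class UpsampleNd(Module):
    """Nearest-neighbour 2x upsampling."""

    def __init__(self, rank: int):
        super().__init__()
        self.rank = rank

    def forward(self, x: Tensor) -> Tensor:
        x = astensor(x)
        out = x.data
        for ax in range(2, 2 + self.rank):
            out = np.repeat(out, 2, axis=ax)
        rank = self.rank
        in_shape = x.data.shape

        def bwd(g):
            gg = g
            for i in range(rank):
                ax = 2 + i
                shp = list(gg.shape)
                shp[ax:ax + 1] = [shp[ax] // 2, 2]
                gg = gg.reshape(shp).sum(axis=ax + 1)
            _accum(x, gg.reshape(in_shape))

        return _make(out, (x,), bwd)


class BatchNorm(Module):
    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self._buffers = {
            "running_mean": np.zeros(num_features),
            "running_var": np.ones(num_features),
        }

    def forward(self, x: Tensor) -> Tensor:
        x = astensor(x)
        xd = x.data
        axes = (0,) + tuple(range(2, xd.ndim))
        bshape = (1, -1) + (1,) * (xd.ndim - 2)
        if self.training:
            mean = xd.mean(axis=axes)
            var = xd.var(axis=axes)
            m = self.momentum
            self._buffers["running_mean"] = \
                (1 - m) * self._buffers["running_mean"] + m * mean
            self._buffers["running_var"] = \
                (1 - m) * self._buffers["running_var"] + m * var
        else:
            mean = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mean.reshape(bshape)) * inv_std.reshape(bshape)
        out = self.gamma.data.reshape(bshape) * xhat + self.beta.data.reshape(bshape)
        gamma, beta = self.gamma, self.beta
        training = self.training
        nr = xd.size // self.num_features

        def bwd(g):
            _accum(gamma, (g * xhat).sum(axis=axes))
            _accum(beta, g.sum(axis=axes))
            if not (x.requires_grad or x._backward is not None):
                return
            dxhat = g * gamma.data.reshape(bshape)
            istd = inv_std.reshape(bshape)
            if training:
                s1 = dxhat.sum(axis=axes, keepdims=True)
                s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                dx = istd / nr * (nr * dxhat - s1 - xhat * s2)
            else:
                dx = dxhat * istd
            _accum(x, dx)

        return _make(out, (x, gamma, beta), bwd)


class Dropout(Module):
    """Inverted dropout; draws masks from the owning network's generator."""

    def __init__(self, p: float):
        super().__init__()
        self.p = float(p)
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return astensor(x)
        if self.rng is None:
            raise RuntimeError("dropout layer has no rng attached")
        x = astensor(x)
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        out = x.data * mask

        def bwd(g):
            _accum(x, g * mask)

        return _make(out, (x,), bwd)
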