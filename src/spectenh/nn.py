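"""Minimal NumPy CNN engine for the slice-enhancement network.

Implements exactly the pieces the encoder-decoder needs — 3x3 same-padding
convolution, ReLU, 2x2 max pooling, nearest-neighbor upsampling, channel
concatenation, a 1x1 linear output convolution — with hand-written backward
passes and an Adam optimizer. Everything runs in float32.

Convolutions use a channels-last layout internally: the padded input is
multiplied once by the (C, 9F) weight matrix (a single contiguous BLAS
call) and the nine shifted slices of the product are summed — equivalent
to im2col but without materializing the 9x-sized patch matrix. The public
interface is channels-first (B, C, H, W), matching how slice stacks are
assembled.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNet2D", "Adam"]


def _conv3_nhwc(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """3x3 same conv. x is (B, H, W, C), w is (9, C, F), kernel-tap major.

    Two equivalent evaluation orders, picked by memory traffic: an im2col
    GEMM (patch matrix has 9C columns) when the input is narrow, or one
    full-grid product with the (C, 9F) weight matrix followed by nine
    shifted-slice adds when the output is narrow.
    """
    bs, h, wd, c = x.shape
    f = w.shape[2]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    if c <= f:
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (B,H,W,C,3,3)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            -1, 9 * c
        )
        out = (cols @ w.reshape(9 * c, f)).reshape(bs, h, wd, f)
    else:
        wmat = np.ascontiguousarray(w.transpose(1, 0, 2)).reshape(c, 9 * f)
        prod = (xp.reshape(-1, c) @ wmat).reshape(bs, h + 2, wd + 2, 9, f)
        out = prod[:, 1 : 1 + h, 1 : 1 + wd, 4, :].copy()
        for k in range(9):
            if k == 4:
                continue
            ky, kx = divmod(k, 3)
            out += prod[:, ky : ky + h, kx : kx + wd, k, :]
    if b is not None:
        out += b
    return out


class _Conv3:
    """3x3 conv (+ optional ReLU). Weights: (9, C, F) tensor + (F,) bias."""

    def __init__(self, name: str, c_in: int, c_out: int, relu: bool = True):
        self.name = name
        self.c_in = c_in
        self.c_out = c_out
        self.relu = relu

    def init_params(self, params: dict, rng: np.random.Generator) -> None:
        std = np.sqrt(2.0 / (self.c_in * 9))
        params[self.name + ".w"] = (
            rng.standard_normal((9, self.c_in, self.c_out)) * std
        ).astype(np.float32)
        params[self.name + ".b"] = np.zeros(self.c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, params: dict, ctx: dict) -> np.ndarray:
        y = _conv3_nhwc(x, params[self.name + ".w"], params[self.name + ".b"])
        if self.relu:
            mask = y > 0
            y *= mask
            ctx[self.name + ".mask"] = mask
        ctx[self.name + ".x"] = x
        return y

    def backward(
        self, dy: np.ndarray, params: dict, ctx: dict, grads: dict
    ) -> np.ndarray:
        if self.relu:
            dy = dy * ctx[self.name + ".mask"]
        x = ctx[self.name + ".x"]
        bs, h, wd, c = x.shape
        f = self.c_out
        dw = np.empty((9, c, f), dtype=np.float32)
        if f <= c:
            # shift the (narrow) output gradient against the full input
            x_flat = x.reshape(-1, c)
            for k in range(9):
                ky, kx = divmod(k, 3)
                # dyp[a, b] = dy[a - ky + 1, b - kx + 1], zero outside
                dyp = np.pad(
                    dy, ((0, 0), (ky, 2 - ky), (kx, 2 - kx), (0, 0))
                )[:, 1 : 1 + h, 1 : 1 + wd, :]
                dw[k] = x_flat.T @ dyp.reshape(-1, f)
        else:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
            dy_flat = dy.reshape(-1, f)
            for k in range(9):
                ky, kx = divmod(k, 3)
                sl = np.ascontiguousarray(xp[:, ky : ky + h, kx : kx + wd, :])
                dw[k] = sl.reshape(-1, c).T @ dy_flat
        grads[self.name + ".w"] = dw
        grads[self.name + ".b"] = dy.reshape(-1, f).sum(axis=0)
        # input gradient: convolution with the 180-degree-flipped kernel
        wflip = np.ascontiguousarray(
            params[self.name + ".w"][::-1].transpose(0, 2, 1)
        )
        return _conv3_nhwc(dy, wflip, None)


class _Conv1:
    """1x1 linear projection (the output layer)."""

    def __init__(self, name: str, c_in: int, c_out: int):
        self.name = name
        self.c_in = c_in
        self.c_out = c_out

    def init_params(self, params: dict, rng: np.random.Generator) -> None:
        std = np.sqrt(2.0 / self.c_in)
        params[self.name + ".w"] = (
            rng.standard_normal((self.c_in, self.c_out)) * std
        ).astype(np.float32)
        params[self.name + ".b"] = np.zeros(self.c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, params: dict, ctx: dict) -> np.ndarray:
        ctx[self.name + ".x"] = x
        return x @ params[self.name + ".w"] + params[self.name + ".b"]

    def backward(
        self, dy: np.ndarray, params: dict, ctx: dict, grads: dict
    ) -> np.ndarray:
        x = ctx[self.name + ".x"]
        grads[self.name + ".w"] = x.reshape(-1, self.c_in).T @ dy.reshape(
            -1, self.c_out
        )
        grads[self.name + ".b"] = dy.reshape(-1, self.c_out).sum(axis=0)
        return dy @ params[self.name + ".w"].T


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b, h, w, c = x.shape
    r = x.reshape(b, h // 2, 2, w // 2, 2, c)
    m = r.max(axis=(2, 4))
    # tie-splitting mask keeps the backward pass deterministic
    mask = (r == m[:, :, None, :, None, :]).astype(np.float32)
    mask /= mask.sum(axis=(2, 4), keepdims=True)
    return m, mask


def _maxpool2_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    b, h2, _, w2, _, c = mask.shape
    d = mask * dy[:, :, None, :, None, :]
    return d.reshape(b, h2 * 2, w2 * 2, c)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample2_backward(dy: np.ndarray) -> np.ndarray:
    b, h, w, c = dy.shape
    return dy.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class UNet2D:
    """Encoder-decoder with concatenation skips.

    ``n_levels`` resolution scales; each encoder scale applies two 3x3
    convolutions with ReLU and (except the bottom) 2x2 max pooling; channel
    counts double per scale from ``base_channels``. The decoder upsamples
    (nearest neighbor, checkerboard-safe), concatenates the matching
    encoder output, and applies two 3x3 convolutions; a linear 1x1
    projection produces the single output slice. Input in-plane size must
    be divisible by 2**n_levels. Inputs/outputs are (B, C, H, W).
    """

    def __init__(
        self,
        in_channels: int = 5,
        n_levels: int = 3,
        base_channels: int = 16,
        seed: int = 0,
    ):
        if n_levels < 2:
            raise ValueError("need at least 2 resolution levels")
        self.in_channels = in_channels
        self.n_levels = n_levels
        self.base_channels = base_channels
        chans = [base_channels * 2**i for i in range(n_levels)]
        self.channels = chans
        self.enc: list[list[_Conv3]] = []
        prev = in_channels
        for i in range(n_levels):
            self.enc.append(
                [
                    _Conv3(f"enc{i}a", prev, chans[i]),
                    _Conv3(f"enc{i}b", chans[i], chans[i]),
                ]
            )
            prev = chans[i]
        self.dec: list[list[_Conv3]] = []
        for i in reversed(range(n_levels - 1)):
            self.dec.append(
                [
                    _Conv3(f"dec{i}a", chans[i + 1] + chans[i], chans[i]),
                    _Conv3(f"dec{i}b", chans[i], chans[i]),
                ]
            )
        self.out_layer = _Conv1("out", chans[0], 1)
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        for block in self.enc + self.dec:
            for layer in block:
                layer.init_params(self.params, rng)
        self.out_layer.init_params(self.params, rng)

    def _check(self, x: np.ndarray) -> None:
        h, w = x.shape[2], x.shape[3]
        div = 2**self.n_levels
        if h % div or w % div:
            raise ValueError(
                f"in-plane size {h}x{w} not divisible by 2^{self.n_levels}"
            )

    # -- core passes (channels-last internally) ----------------------------
    def _forward_nhwc(self, h: np.ndarray, ctx: dict) -> np.ndarray:
        skips = []
        for i in range(self.n_levels - 1):
            for layer in self.enc[i]:
                h = layer.forward(h, self.params, ctx)
            skips.append(h)
            h, mask = _maxpool2(h)
            ctx[f"pool{i}.mask"] = mask
        for layer in self.enc[-1]:
            h = layer.forward(h, self.params, ctx)
        for j, i in enumerate(reversed(range(self.n_levels - 1))):
            h = _upsample2(h)
            ctx[f"cat{i}.split"] = h.shape[3]
            h = np.concatenate([h, skips[i]], axis=3)
            for layer in self.dec[j]:
                h = layer.forward(h, self.params, ctx)
        return self.out_layer.forward(h, self.params, ctx)

    def _backward_nhwc(self, dy: np.ndarray, ctx: dict) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        d = self.out_layer.backward(dy, self.params, ctx, grads)
        dskips: dict[int, np.ndarray] = {}
        # decoder blocks in reverse of their forward order (shallowest first)
        for j in reversed(range(len(self.dec))):
            i = self.n_levels - 2 - j
            for layer in reversed(self.dec[j]):
                d = layer.backward(d, self.params, ctx, grads)
            split = ctx[f"cat{i}.split"]
            dskips[i] = d[..., split:]
            d = _upsample2_backward(np.ascontiguousarray(d[..., :split]))
        for layer in reversed(self.enc[-1]):
            d = layer.backward(d, self.params, ctx, grads)
        for i in reversed(range(self.n_levels - 1)):
            d = _maxpool2_backward(d, ctx[f"pool{i}.mask"])
            d = d + dskips[i]
            for layer in reversed(self.enc[i]):
                d = layer.backward(d, self.params, ctx, grads)
        return grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Inference pass: (B, C, H, W) in, (B, 1, H, W) out."""
        self._check(x)
        h = np.ascontiguousarray(
            x.transpose(0, 2, 3, 1), dtype=np.float32
        )
        ctx: dict = {}
        y = self._forward_nhwc(h, ctx)
        return y.transpose(0, 3, 1, 2)

    def loss_and_grads(
        self, x: np.ndarray, target: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Voxel-wise MSE loss and parameter gradients for one minibatch.

        ``x`` is (B, C, H, W), ``target`` (B, 1, H, W).
        """
        self._check(x)
        h = np.ascontiguousarray(x.transpose(0, 2, 3, 1), dtype=np.float32)
        t = np.ascontiguousarray(target.transpose(0, 2, 3, 1), dtype=np.float32)
        ctx: dict = {}
        y = self._forward_nhwc(h, ctx)
        diff = y - t
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        dy = (2.0 / diff.size) * diff
        grads = self._backward_nhwc(dy.astype(np.float32), ctx)
        return loss, grads

    # -- state --------------------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = weights[k].astype(np.float32).copy()

    def spec_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "n_levels": self.n_levels,
            "base_channels": self.base_channels,
        }


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1c
            vhat = self.v[k] / b2c
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32
            )
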