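"""Convolutional building blocks with hand-written backward passes.

All spatial ops take NCHW batches.  Convolutions are stride-1 with "same"
padding for odd kernels (the only configuration the encoder/decoder blocks
use); upsampling is a kernel-2, stride-2 transposed convolution, whose
non-overlapping taps make both passes simple einsum reshapes.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "conv_transpose2x2", "max_pool2x2", "batch_norm2d"]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, pad: int | None = None) -> Tensor:
    """Stride-1 2D convolution (cross-correlation), default "same" padding.

    ``weight`` has shape (out_channels, in_channels, k, k) with k odd.
    Implemented as k*k shifted channel contractions rather than im2col,
    which avoids materialising the patch matrix.
    """
    k = weight.data.shape[-1]
    if pad is None:
        pad = (k - 1) // 2
    n, c, h, w = x.data.shape
    oc = weight.data.shape[0]
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        if pad
        else x.data
    )
    oh, ow = h + 2 * pad - k + 1, w + 2 * pad - k + 1
    out_data = np.empty((n, oc, oh, ow), dtype=x.data.dtype)
    out_data[:] = bias.data[None, :, None, None]
    for dy in range(k):
        for dx in range(k):
            xs = xp[:, :, dy : dy + oh, dx : dx + ow]
            out_data += np.einsum(
                "nchw,oc->nohw", xs, weight.data[:, :, dy, dx], optimize=True
            )

    def back(g: np.ndarray) -> None:
        if bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.empty_like(weight.data)
            for dy in range(k):
                for dx in range(k):
                    xs = xp[:, :, dy : dy + oh, dx : dx + ow]
                    dw[:, :, dy, dx] = np.einsum(
                        "nohw,nchw->oc", g, xs, optimize=True
                    )
            weight.accumulate_grad(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for dy in range(k):
                for dx in range(k):
                    dxp[:, :, dy : dy + oh, dx : dx + ow] += np.einsum(
                        "nohw,oc->nchw", g, weight.data[:, :, dy, dx], optimize=True
                    )
            x.accumulate_grad(
                dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp
            )

    return Tensor(out_data, parents=(x, weight, bias), backward=back)


def conv_transpose2x2(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Kernel-2, stride-2 transposed convolution: doubles H and W.

    ``weight`` has shape (in_channels, out_channels, 2, 2).  Because the
    stride equals the kernel size the output taps never overlap.
    """
    n, c, h, w = x.data.shape
    oc = weight.data.shape[1]
    # (N,H,W,O,2,2)
    out6 = np.tensordot(x.data, weight.data, axes=([1], [0]))
    out_data = (
        out6.transpose(0, 3, 1, 4, 2, 5).reshape(n, oc, 2 * h, 2 * w)
        + bias.data[None, :, None, None]
    )

    def back(g: np.ndarray) -> None:
        g6 = g.reshape(n, oc, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        if bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.tensordot(x.data, g6, axes=([0, 2, 3], [0, 1, 2]))
            weight.accumulate_grad(dw)  # (C, O, 2, 2)
        if x.requires_grad:
            dx = np.tensordot(g6, weight.data, axes=([3, 4, 5], [1, 2, 3]))
            x.accumulate_grad(dx.transpose(0, 3, 1, 2))

    return Tensor(out_data, parents=(x, weight, bias), backward=back)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 needs even spatial dims, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def back(g: np.ndarray) -> None:
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x.accumulate_grad(gx.reshape(n, c, h, w))

    return Tensor(out_data, parents=(x,), backward=back)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    In training mode batch statistics are used and the running buffers are
    updated in place; in evaluation mode the running buffers are used, making
    the op a fixed affine map.
    """
    axes = (0, 2, 3)
    gshape = (1, -1, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(gshape)) * inv_std.reshape(gshape)
    out_data = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def back(g: np.ndarray) -> None:
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(gshape)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                term = (
                    gxhat
                    - gxhat.mean(axis=axes, keepdims=True)
                    - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True) / m
                )
                x.accumulate_grad(term * inv_std.reshape(gshape))
            else:
                x.accumulate_grad(gxhat * inv_std.reshape(gshape))

    return Tensor(out_data, parents=(x, gamma, beta), backward=back)
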