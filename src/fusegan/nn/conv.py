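"""3-D convolution and transposed convolution as autodiff operations.

Kernels are gathered/scattered with k^3 strided-slice loops (27 iterations
for the 3x3x3 filters used throughout), which keeps both directions fully
vectorised over batch, channel and spatial axes.

Weight layouts follow the common deep-learning convention:
  conv3d            weight (O, C, k, k, k)   input (N, C, D, H, W)
  conv_transpose3d  weight (C, O, k, k, k)   input (N, C, D, H, W)
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["conv3d", "conv_transpose3d", "conv_out_size", "conv_transpose_out_size"]


def conv_out_size(size: int, kernel: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - kernel) // stride + 1


def conv_transpose_out_size(
    size: int, kernel: int, stride: int, pad: int, output_padding: int
) -> int:
    return (size - 1) * stride - 2 * pad + kernel + output_padding


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    width = [(0, 0), (0, 0)] + [(pad, pad)] * 3
    return np.pad(x, width)


def _gather(xp: np.ndarray, kernel: int, stride: int, out_sp: tuple[int, int, int]):
    """Patch tensor (N, C, k, k, k, Do, Ho, Wo) from padded input."""
    n, c = xp.shape[:2]
    do, ho, wo = out_sp
    cols = np.empty((n, c, kernel, kernel, kernel, do, ho, wo), dtype=xp.dtype)
    for a in range(kernel):
        for b in range(kernel):
            for cc in range(kernel):
                cols[:, :, a, b, cc] = xp[
                    :,
                    :,
                    a : a + do * stride : stride,
                    b : b + ho * stride : stride,
                    cc : cc + wo * stride : stride,
                ]
    return cols


def _scatter(
    gcols: np.ndarray,
    padded_shape: tuple[int, ...],
    kernel: int,
    stride: int,
) -> np.ndarray:
    """Adjoint of :func:`_gather`: scatter-add patches into the padded array."""
    out = np.zeros(padded_shape, dtype=gcols.dtype)
    do, ho, wo = gcols.shape[-3:]
    for a in range(kernel):
        for b in range(kernel):
            for cc in range(kernel):
                out[
                    :,
                    :,
                    a : a + do * stride : stride,
                    b : b + ho * stride : stride,
                    cc : cc + wo * stride : stride,
                ] += gcols[:, :, a, b, cc]
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, pad: int) -> Tensor:
    kernel = w.data.shape[2]
    out_sp = tuple(conv_out_size(s, kernel, stride, pad) for s in x.data.shape[2:])
    xp = _pad_spatial(x.data, pad)
    cols = _gather(xp, kernel, stride, out_sp)
    # (N,C,k,k,k,Do,Ho,Wo) x (O,C,k,k,k) -> (N,Do,Ho,Wo,O)
    out_data = np.tensordot(cols, w.data, axes=([1, 2, 3, 4], [1, 2, 3, 4]))
    out_data = np.moveaxis(out_data, -1, 1)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(
        out_data,
        requires_grad=any(p.requires_grad for p in parents),
        _parents=parents,
    )

    def _bw(g):
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            # (N,O,Do,Ho,Wo) x (N,C,k,k,k,Do,Ho,Wo) over N,Do,Ho,Wo
            gw = np.tensordot(g, cols, axes=([0, 2, 3, 4], [0, 5, 6, 7]))
            w._accumulate(gw)
        if x.requires_grad:
            # (N,O,...) x (O,C,k,k,k) -> (N,...,C,k,k,k)
            gcols = np.tensordot(g, w.data, axes=([1], [0]))
            gcols = np.moveaxis(gcols, (4, 5, 6, 7), (1, 2, 3, 4))
            gxp = _scatter(gcols, xp.shape, kernel, stride)
            if pad:
                gxp = gxp[:, :, pad:-pad, pad:-pad, pad:-pad]
            x._accumulate(gxp)

    out._backward = _bw
    return out


def conv_transpose3d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None,
    stride: int,
    pad: int,
    output_padding: int,
) -> Tensor:
    kernel = w.data.shape[2]
    in_sp = x.data.shape[2:]
    full_sp = tuple((s - 1) * stride + kernel for s in in_sp)
    out_sp = tuple(
        conv_transpose_out_size(s, kernel, stride, pad, output_padding) for s in in_sp
    )
    if output_padding > pad:
        raise ValueError("output_padding must not exceed padding")

    n = x.data.shape[0]
    cout = w.data.shape[1]
    # contributions[n, :, a + i*stride, ...] += x[n, ci, i, ...] * w[ci, :, a, b, c]
    # i.e. scatter of per-offset tensordot results.
    contrib = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N,Di,Hi,Wi,Cout,k,k,k)
    contrib = np.moveaxis(contrib, (4, 5, 6, 7), (1, 2, 3, 4))  # (N,Cout,k,k,k,Di,Hi,Wi)
    full = _scatter(contrib, (n, cout) + full_sp, kernel, stride)
    sl = tuple(slice(pad, pad + o) for o in out_sp)
    out_data = full[(slice(None), slice(None)) + sl]
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(
        out_data,
        requires_grad=any(p.requires_grad for p in parents),
        _parents=parents,
    )

    def _bw(g):
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        gfull = np.zeros((n, cout) + full_sp, dtype=g.dtype)
        gfull[(slice(None), slice(None)) + sl] = g
        gcols = _gather(gfull, kernel, stride, in_sp)  # (N,Cout,k,k,k,Di,Hi,Wi)
        if x.requires_grad:
            gx = np.tensordot(gcols, w.data, axes=([1, 2, 3, 4], [1, 2, 3, 4]))
            x._accumulate(np.moveaxis(gx, -1, 1))
        if w.requires_grad:
            # sum over N and input positions: (Cin, Cout, k, k, k)
            gw = np.tensordot(x.data, gcols, axes=([0, 2, 3, 4], [0, 5, 6, 7]))
            w._accumulate(gw)

    out._backward = _bw
    return out
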