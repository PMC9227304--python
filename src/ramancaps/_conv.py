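"""Minimal valid-mode 2-D convolution with explicit forward/backward,
implemented via im2col so the heavy work is one matrix product."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv_output_size(n: int, k: int, stride: int) -> int:
    return (n - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*k*k, P) patch matrix, P = oh*ow."""
    windows = sliding_window_view(x, (k, k), axis=(2, 3))  # (B,C,H-k+1,W-k+1,k,k)
    windows = windows[:, :, ::stride, ::stride, :, :]
    b, c, oh, ow, _, _ = windows.shape
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, oh * ow)
    return np.ascontiguousarray(cols)


def conv2d_forward(
    x: np.ndarray, w: np.ndarray, bias: np.ndarray, stride: int
) -> tuple[np.ndarray, np.ndarray]:
    """Valid convolution. Returns (out, cols) with cols cached for backward.

    x: (B, Cin, H, W); w: (Cout, Cin, k, k); bias: (Cout,);
    out: (B, Cout, oh, ow).
    """
    bsz, cin, h, wd = x.shape
    cout, cin2, k, _ = w.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin2}")
    oh, ow = conv_output_size(h, k, stride), conv_output_size(wd, k, stride)
    cols = im2col(x, k, stride)  # (B, Cin*k*k, P)
    wm = w.reshape(cout, -1)
    out = np.einsum("of,bfp->bop", wm, cols, optimize=True) + bias[None, :, None]
    return out.reshape(bsz, cout, oh, ow), cols


def conv2d_backward(
    dout: np.ndarray,
    cols: np.ndarray,
    x_shape: tuple[int, ...],
    w: np.ndarray,
    stride: int,
    need_dx: bool = True,
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Gradients of conv2d_forward. Returns (dx, dw, dbias)."""
    bsz, cin, h, wd = x_shape
    cout, _, k, _ = w.shape
    oh, ow = conv_output_size(h, k, stride), conv_output_size(wd, k, stride)
    dflat = dout.reshape(bsz, cout, oh * ow)
    dbias = dflat.sum(axis=(0, 2))
    dw = np.einsum("bop,bfp->of", dflat, cols, optimize=True).reshape(w.shape)
    if not need_dx:
        return None, dw, dbias
    # scatter column gradients back onto the input grid
    dcols = np.einsum("of,bop->bfp", w.reshape(cout, -1), dflat, optimize=True)
    dcols = dcols.reshape(bsz, cin, k, k, oh, ow)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    for ki in range(k):
        for kj in range(k):
            dx[:, :, ki : ki + stride * oh : stride, kj : kj + stride * ow : stride] += dcols[
                :, :, ki, kj, :, :
            ]
    return dx, dw, dbias
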