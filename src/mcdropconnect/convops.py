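"""Low-level image operators: im2col convolution patches, 2x2 max-pooling and
nearest-neighbour upsampling, with the backward passes needed for training.

All convolutions are stride-1 with "same" zero padding and odd kernel sizes, which
is all the miniature architectures in this package require.  A convolution is
expressed as an affine map over im2col patch rows so the Bernoulli weight-masking
machinery (one mask element per kernel weight) applies identically to dense and
convolutional layers.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidParameterError, ShapeMismatchError


def im2col(x: np.ndarray, kernel_size: int) -> np.ndarray:
    """Extract kernel_size x kernel_size patches around every pixel.

    Parameters
    ----------
    x : array, shape (N, H, W, C)
    kernel_size : odd int

    Returns
    -------
    array, shape (N, H, W, kernel_size**2 * C)
    """
    if x.ndim != 4:
        raise ShapeMismatchError(f"expected NHWC input, got shape {x.shape}")
    if kernel_size % 2 != 1 or kernel_size < 1:
        raise InvalidParameterError(f"kernel_size must be odd and positive, got {kernel_size}")
    n, h, w, c = x.shape
    pad = kernel_size // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    patches = [
        xp[:, i : i + h, j : j + w, :]
        for i in range(kernel_size)
        for j in range(kernel_size)
    ]
    return np.concatenate(patches, axis=-1).reshape(n, h, w, kernel_size * kernel_size * c)


def col2im(dcols: np.ndarray, kernel_size: int, n_channels: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter patch gradients back onto the image."""
    n, h, w, _ = dcols.shape
    pad = kernel_size // 2
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, n_channels), dtype=dcols.dtype)
    dcols = dcols.reshape(n, h, w, kernel_size * kernel_size, n_channels)
    idx = 0
    for i in range(kernel_size):
        for j in range(kernel_size):
            dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, idx, :]
            idx += 1
    return dxp[:, pad : pad + h, pad : pad + w, :]


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling with stride 2.  Returns (pooled, argmax one-hot cache)."""
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ShapeMismatchError(f"maxpool2 needs even spatial dims, got {(h, w)}")
    blocks = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    blocks = blocks.reshape(n, h // 2, w // 2, 4, c)
    arg = np.argmax(blocks, axis=3)
    out = np.take_along_axis(blocks, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    onehot = np.zeros_like(blocks)
    np.put_along_axis(onehot, arg[:, :, :, None, :], 1.0, axis=3)
    return out, onehot


def maxpool2_backward(dout: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    n, h2, w2, _, c = onehot.shape
    dblocks = onehot * dout[:, :, :, None, :]
    dblocks = dblocks.reshape(n, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    return dblocks.reshape(n, h2 * 2, w2 * 2, c)


def upsample2(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour x2 upsampling."""
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
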