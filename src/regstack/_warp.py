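"""Numba kernels for rigid warping and the fused warp+MSE registration cost.

These kernels are the inner loop of the registration search: a single
GA-CPSO run evaluates the cost thousands of times, so the warp and the
mean-squared-error reduction are fused into one pass over the pixels.

Conventions (shared with :mod:`regstack.imaging`):

* x = column index, y = row index, both 0-based;
* rotation angle theta is in radians here, positive = counter-clockwise
  in the displayed orientation (y axis pointing down);
* rotation is about the geometric image center ((n-1)/2, (m-1)/2),
  applied before the translation (tx, ty);
* samples falling outside the moving image's support are treated as 0,
  with bilinear blending at the support edge.  This matches
  ``scipy.ndimage.affine_transform(order=1, mode='grid-constant', cval=0)``
  to machine precision, which the test suite verifies.
"""

import math

import numba
import numpy as np

__all__ = ["warp_bilinear", "warp_nearest", "warp_mse"]


@numba.njit(cache=True)
def warp_bilinear(moving, cos_t, sin_t, tx, ty):
    """Rotate ``moving`` about its center then translate, bilinear interpolation."""
    m, n = moving.shape
    out = np.zeros((m, n))
    cy = (m - 1) / 2.0
    cx = (n - 1) / 2.0
    for r in range(m):
        for c in range(n):
            xo = c - cx - tx
            yo = r - cy - ty
            xi = cos_t * xo - sin_t * yo + cx
            yi = sin_t * xo + cos_t * yo + cy
            x0 = math.floor(xi)
            y0 = math.floor(yi)
            fx = xi - x0
            fy = yi - y0
            ix0 = int(x0)
            iy0 = int(y0)
            v = 0.0
            w00 = (1.0 - fx) * (1.0 - fy)
            w10 = fx * (1.0 - fy)
            w01 = (1.0 - fx) * fy
            w11 = fx * fy
            if 0 <= iy0 < m and 0 <= ix0 < n:
                v += w00 * moving[iy0, ix0]
            if 0 <= iy0 < m and 0 <= ix0 + 1 < n:
                v += w10 * moving[iy0, ix0 + 1]
            if 0 <= iy0 + 1 < m and 0 <= ix0 < n:
                v += w01 * moving[iy0 + 1, ix0]
            if 0 <= iy0 + 1 < m and 0 <= ix0 + 1 < n:
                v += w11 * moving[iy0 + 1, ix0 + 1]
            out[r, c] = v
    return out


@numba.njit(cache=True)
def warp_nearest(moving, cos_t, sin_t, tx, ty):
    """Same map as :func:`warp_bilinear` with nearest-neighbour sampling."""
    m, n = moving.shape
    out = np.zeros((m, n))
    cy = (m - 1) / 2.0
    cx = (n - 1) / 2.0
    for r in range(m):
        for c in range(n):
            xo = c - cx - tx
            yo = r - cy - ty
            xi = cos_t * xo - sin_t * yo + cx
            yi = sin_t * xo + cos_t * yo + cy
            ix = int(round(xi))
            iy = int(round(yi))
            if 0 <= iy < m and 0 <= ix < n:
                out[r, c] = moving[iy, ix]
    return out


@numba.njit(cache=True, fastmath=True)
def warp_mse(fixed, moving, cos_t, sin_t, tx, ty):
    """Mean squared error between ``fixed`` and the warped ``moving`` image.

    Equivalent to ``np.mean((fixed - warp_bilinear(moving, ...))**2)`` without
    materialising the warped image.
    """
    m, n = fixed.shape
    cy = (m - 1) / 2.0
    cx = (n - 1) / 2.0
    acc = 0.0
    for r in range(m):
        for c in range(n):
            xo = c - cx - tx
            yo = r - cy - ty
            xi = cos_t * xo - sin_t * yo + cx
            yi = sin_t * xo + cos_t * yo + cy
            x0 = math.floor(xi)
            y0 = math.floor(yi)
            fx = xi - x0
            fy = yi - y0
            ix0 = int(x0)
            iy0 = int(y0)
            v = 0.0
            w00 = (1.0 - fx) * (1.0 - fy)
            w10 = fx * (1.0 - fy)
            w01 = (1.0 - fx) * fy
            w11 = fx * fy
            if 0 <= iy0 < m and 0 <= ix0 < n:
                v += w00 * moving[iy0, ix0]
            if 0 <= iy0 < m and 0 <= ix0 + 1 < n:
                v += w10 * moving[iy0, ix0 + 1]
            if 0 <= iy0 + 1 < m and 0 <= ix0 < n:
                v += w01 * moving[iy0 + 1, ix0]
            if 0 <= iy0 + 1 < m and 0 <= ix0 + 1 < n:
                v += w11 * moving[iy0 + 1, ix0 + 1]
            d = fixed[r, c] - v
            acc += d * d
    return acc / (m * n)
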