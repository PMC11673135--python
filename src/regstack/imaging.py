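"""Image representation, grayscale conversion, denoising and rigid transforms.

The universal operand is a plain 2-D ``float64`` numpy array of intensities on
the nominal 0-255 scale ("Image2D").  Intensities stay floating point through
the whole pipeline; quantisation to 8 bit happens only on export.

Coordinate convention: x = column index, y = row index, 0-based.  A rigid
transform rotates by ``theta`` degrees (positive = counter-clockwise in the
displayed orientation) about the geometric image center ((n-1)/2, (m-1)/2)
and then translates by (tx, ty) pixels.  Pixels sampled outside the source
support are filled with 0 — the black borders visible around a registered
frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._warp import warp_bilinear, warp_nearest

__all__ = [
    "RigidTransform",
    "as_image",
    "to_grayscale",
    "mean_filter_4x4",
    "apply_rigid_transform",
    "transform_valid_mask",
    "compose_inverse_check",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-motion parameters: translation (tx, ty) in pixels, rotation in degrees.

    The triple is the optimisation variable of the registration search.
    ``theta`` is interpreted modulo 360 but stored as given.
    """

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tx", "ty", "theta"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite transform parameter {name}={v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.theta], dtype=float)

    @classmethod
    def from_array(cls, p) -> "RigidTransform":
        tx, ty, theta = (float(v) for v in p)
        return cls(tx, ty, theta)

    @property
    def is_identity(self) -> bool:
        return self.tx == 0.0 and self.ty == 0.0 and self.theta % 360.0 == 0.0

    def inverse(self) -> "RigidTransform":
        """Transform undoing this one (rotate -theta, then counter-translate)."""
        th = math.radians(self.theta)
        ct, st = math.cos(th), math.sin(th)
        # forward: p' = R(theta) p + t  =>  inverse: p = R(-theta) p' - R(-theta) t
        itx = -(ct * self.tx - st * self.ty)
        ity = -(st * self.tx + ct * self.ty)
        return RigidTransform(itx, ity, -self.theta)


def as_image(pixels, *, min_size: int = 2) -> np.ndarray:
    """Validate and convert to a C-contiguous float64 Image2D."""
    arr = np.ascontiguousarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise ValueError(f"image {arr.shape} smaller than minimum {min_size}x{min_size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    return arr


def to_grayscale(rgb_frame) -> np.ndarray:
    """Average the three colour channels into a single-channel image.

    Accepts an (m, n, 3) raster or three separate equal-shape channels.
    """
    arr = np.asarray(rgb_frame, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        channels = [arr[..., k] for k in range(3)]
    elif arr.ndim == 3 and arr.shape[0] == 3:
        channels = [arr[k] for k in range(3)]
    else:
        raise ValueError(f"expected a 3-channel raster, got shape {arr.shape}")
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise ValueError(f"channel shape mismatch: {shapes}")
    return as_image((channels[0] + channels[1] + channels[2]) / 3.0)


def mean_filter_4x4(img) -> np.ndarray:
    """Replace each pixel by the mean of its local 4x4 neighbourhood.

    The even kernel is anchored at offset (1, 1) within the window (the
    top-left pixel of the central 2x2), i.e. pixel (r, c) averages rows
    r-1..r+2 and columns c-1..c+2.  Borders use reflect padding so the
    output keeps the input shape.
    """
    from scipy import ndimage

    img = as_image(img, min_size=4)
    # scipy origin semantics: size=4 with origin=0 covers offsets {-2..1};
    # origin=-1 shifts the window to {-1..2}, the documented anchoring.
    return ndimage.uniform_filter(img, size=4, mode="reflect", origin=-1)


def apply_rigid_transform(img, t: RigidTransform, *, order: str = "bilinear") -> np.ndarray:
    """Rotate about the image center, then translate; zero fill outside support.

    ``order`` selects the interpolation scheme: "bilinear" (default; smooth
    cost surfaces for the optimisers) or "nearest".
    """
    img = as_image(img)
    if order not in ("bilinear", "nearest"):
        raise ValueError(f"unknown interpolation order {order!r}")
    if t.is_identity and float(t.theta) == 0.0:
        return img.copy()
    th = math.radians(t.theta)
    kern = warp_bilinear if order == "bilinear" else warp_nearest
    return kern(img, math.cos(th), math.sin(th), float(t.tx), float(t.ty))


def transform_valid_mask(shape, t: RigidTransform) -> np.ndarray:
    """Boolean mask of output pixels whose source sample lies inside the image.

    Pixels outside the mask were zero-filled by :func:`apply_rigid_transform`;
    quality metrics exclude them so synthetic borders do not masquerade as
    edges.
    """
    m, n = shape
    cy, cx = (m - 1) / 2.0, (n - 1) / 2.0
    th = math.radians(t.theta)
    ct, st = math.cos(th), math.sin(th)
    cgrid, rgrid = np.meshgrid(np.arange(n, dtype=float), np.arange(m, dtype=float))
    xo = cgrid - cx - t.tx
    yo = rgrid - cy - t.ty
    xi = ct * xo - st * yo + cx
    yi = st * xo + ct * yo + cy
    return (xi >= 0) & (xi <= n - 1) & (yi >= 0) & (yi <= m - 1)


def compose_inverse_check(t: RigidTransform, img) -> float:
    """Round-trip residual: MSE between ``img`` and warp(warp(img, t), t^-1).

    Evaluated only over the region valid under both warps.  Used by the test
    suite to validate the transform algebra on smooth images.
    """
    img = as_image(img)
    fwd = apply_rigid_transform(img, t)
    back = apply_rigid_transform(fwd, t.inverse())
    mask = transform_valid_mask(img.shape, t.inverse()) & transform_valid_mask(img.shape, t)
    # also require the forward-warp source of each surviving pixel to be valid:
    # compose the two masks by warping the forward validity back.
    fwd_valid = transform_valid_mask(img.shape, t)
    back_valid = apply_rigid_transform(fwd_valid.astype(float), t.inverse(), order="nearest") > 0.5
    mask = mask & back_valid & fwd_valid
    if mask.sum() < 16:
        raise ValueError("degenerate overlap region in round-trip check")
    d = img[mask] - back[mask]
    return float(np.mean(d * d))
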