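"""Similarity and image-quality metrics for registration and accumulation.

Two families:

* similarity between a fixed and a (registered) moving image — MSE (the
  registration cost), Pearson correlation, mutual information, RMSE, and the
  parameter-space registration accuracy;
* single-image quality/sharpness — gray level (mean intensity), standard
  deviation, Shannon entropy, energy of gradient (EOG), Brenner gradient and
  the multiple of the modulus of gray difference (MMD).

All metrics operate on float intensities on the nominal 0-255 scale.
Intensity histograms (entropy, mutual information) quantise values to an
evenly spaced level grid by round-half-even before counting, so that the
self-information identity MI(a, a) == entropy(a) holds exactly at matched
binning.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .imaging import RigidTransform, as_image

__all__ = [
    "mse",
    "rmse",
    "correlation_coefficient",
    "joint_histogram",
    "mutual_information",
    "registration_accuracy",
    "gray_level",
    "standard_deviation",
    "entropy",
    "energy_of_gradient",
    "brenner_gradient",
    "mmd",
    "quality_metrics",
    "metric_report",
]

QUALITY_METRICS = ("eog", "brenner", "gray_level", "sd", "entropy")


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shape mismatch: {a.shape} vs {b.shape}")


def mse(fixed, moving, t: RigidTransform | None = None) -> float:
    """Mean squared intensity difference between ``fixed`` and transform(moving).

    With ``t`` None or the identity this is the plain pixelwise MSE; otherwise
    the moving image is rigidly warped (zero fill outside support) before the
    comparison.  This is the cost the GA-CPSO search minimises.
    """
    fixed = as_image(fixed)
    moving = as_image(moving)
    _check_same_shape(fixed, moving)
    if t is None or t.is_identity:
        d = fixed - moving
        return float(np.mean(d * d))
    from ._warp import warp_mse

    th = math.radians(t.theta)
    return float(warp_mse(fixed, moving, math.cos(th), math.sin(th), float(t.tx), float(t.ty)))


def rmse(a, b) -> float:
    """Root mean square pixelwise difference (square root of the identity MSE)."""
    return math.sqrt(mse(a, b))


def correlation_coefficient(a, b) -> float:
    """Pearson correlation of the flattened intensities, in [-1, 1].

    Undefined (raises) when either image has zero variance.
    """
    a = as_image(a).ravel()
    b = as_image(b).ravel()
    if a.shape != b.shape:
        raise ValueError("image shape mismatch")
    da = a - a.mean()
    db = b - b.mean()
    va = float(np.dot(da, da))
    vb = float(np.dot(db, db))
    if va == 0.0 or vb == 0.0:
        raise ValueError("correlation undefined: zero intensity variance")
    return float(np.clip(np.dot(da, db) / math.sqrt(va * vb), -1.0, 1.0))


def _quantize(a: np.ndarray, bins: int, value_range: tuple[float, float]) -> np.ndarray:
    """Round-half-even assignment to a ``bins``-point grid spanning value_range."""
    lo, hi = value_range
    if hi <= lo:
        raise ValueError("empty value range")
    step = (hi - lo) / (bins - 1)
    idx = np.rint((np.asarray(a, dtype=float) - lo) / step).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def joint_histogram(a, b, bins: int = 256, value_range: tuple[float, float] = (0.0, 255.0)) -> np.ndarray:
    """bins x bins joint count matrix of the two images' quantised intensities.

    Marginals (row/column sums) equal each image's own 1-D level histogram,
    and the total count equals the number of pixels compared.
    """
    a = as_image(a)
    b = as_image(b)
    _check_same_shape(a, b)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    ia = _quantize(a.ravel(), bins, value_range)
    ib = _quantize(b.ravel(), bins, value_range)
    counts = np.bincount(ia * bins + ib, minlength=bins * bins)
    return counts.reshape(bins, bins)


def mutual_information(a, b, bins: int = 256, value_range: tuple[float, float] = (0.0, 255.0)) -> float:
    """Mutual information in bits from the joint intensity histogram.

    Cells with zero joint probability contribute 0.  Non-negative; equals the
    entropy of ``a`` when ``b`` is ``a`` at the same binning.
    """
    h = joint_histogram(a, b, bins, value_range).astype(float)
    n = h.sum()
    if n == 0:
        raise ValueError("empty joint histogram")
    pxy = h / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    ratio = pxy[nz] / (px[:, None] * py[None, :])[nz]
    return float(np.sum(pxy[nz] * np.log2(ratio)))


def registration_accuracy(
    true_t: RigidTransform, est_t: RigidTransform, *, zero_policy: str = "raise"
) -> float:
    """Accuracy (%) of a recovered rigid transform against ground truth.

    ``A = 100 - (100/3) * (|X-x|/|X| + |Y-y|/|Y| + |R-r|/|R|)`` where
    (X, Y, R) are the true parameters and (x, y, r) the estimates.  Perfect
    recovery gives 100; each term is the relative error of one parameter,
    with absolute values in the denominators so negative true parameters
    stay meaningful.

    A true parameter of exactly 0 makes its relative-error term undefined;
    by default this raises.  ``zero_policy='absolute'`` substitutes the
    absolute error for such terms instead (documented fallback, off by
    default).
    """
    if zero_policy not in ("raise", "absolute"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    true = true_t.as_array()
    est = est_t.as_array()
    terms = np.empty(3)
    for k in range(3):
        if true[k] == 0.0:
            if zero_policy == "raise":
                raise ValueError(
                    "registration_accuracy undefined: true parameter "
                    f"{('tx', 'ty', 'theta')[k]} is 0 (see zero_policy)"
                )
            terms[k] = abs(est[k] - true[k])
        else:
            terms[k] = abs(est[k] - true[k]) / abs(true[k])
    return float(100.0 - 100.0 / 3.0 * terms.sum())


def gray_level(img) -> float:
    """Mean intensity of the image (grayscale-level summary of brightness)."""
    return float(np.mean(as_image(img)))


def standard_deviation(img) -> float:
    """Population standard deviation of intensities about the image mean."""
    return float(np.std(as_image(img)))


def entropy(img, levels: int = 256, value_range: tuple[float, float] = (0.0, 255.0)) -> float:
    """Shannon entropy (bits) of the quantised intensity histogram.

    Intensities are assigned round-half-even to a ``levels``-point grid over
    ``value_range`` before counting; empty levels contribute 0.
    """
    img = as_image(img)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    idx = _quantize(img.ravel(), levels, value_range)
    counts = np.bincount(idx, minlength=levels).astype(float)
    p = counts / counts.sum()
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def energy_of_gradient(img) -> float:
    """Sum of squared first differences along both axes (sharpness energy).

    Boundary terms whose neighbour would fall outside the image are omitted.
    """
    img = as_image(img)
    dr = np.diff(img, axis=0)
    dc = np.diff(img, axis=1)
    return float(np.sum(dr * dr) + np.sum(dc * dc))


def brenner_gradient(img) -> float:
    """Sum of squared two-pixel-lag differences along the row axis (focus measure)."""
    img = as_image(img)
    if img.shape[0] < 3:
        raise ValueError("Brenner gradient needs at least 3 rows")
    d = img[2:, :] - img[:-2, :]
    return float(np.sum(d * d))


def mmd(img) -> float:
    """Sum of products of orthogonal absolute differences (contrast measure)."""
    img = as_image(img)
    dv = np.abs(img[1:, :-1] - img[:-1, :-1])  # |f(x,y) - f(x+1,y)|
    dh = np.abs(img[:-1, 1:] - img[:-1, :-1])  # |f(x,y) - f(x,y+1)|
    return float(np.sum(dv * dh))


def quality_metrics(img, levels: int = 256) -> dict[str, float]:
    """The five accumulation-quality metrics as a dict (EOG, Brenner, GL, SD, entropy)."""
    img = as_image(img)
    return {
        "eog": energy_of_gradient(img),
        "brenner": brenner_gradient(img),
        "gray_level": gray_level(img),
        "sd": standard_deviation(img),
        "entropy": entropy(img, levels=levels),
    }


def metric_report(images: dict[str, np.ndarray], levels: int = 256) -> pd.DataFrame:
    """Tidy metric table: one row per (image label, metric)."""
    rows = []
    for label, img in images.items():
        for name, value in quality_metrics(img, levels=levels).items():
            rows.append({"image": label, "metric": name, "value": value})
    return pd.DataFrame(rows, columns=["image", "metric", "value"])
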