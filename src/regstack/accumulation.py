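"""Frame accumulation and SNR accounting, with and without prior registration.

Accumulating m frames sums corresponding pixels in a wide float
representation (no 8-bit wraparound).  For independent zero-mean noise the
noise standard deviation of the mean falls as sigma/sqrt(m), so the SNR rises
by sqrt(m).  Quality metrics are computed on the mean-normalised accumulation
by default so the frame count does not trivially inflate gradient metrics;
the raw sum is retained.

When frames were registered first, their zero-filled borders are excluded
from quality metrics through a validity-mask intersection, so synthetic
border edges cannot masquerade as image sharpness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import as_image, transform_valid_mask
from .metrics import quality_metrics
from .registration import RegistrationResult, register_sequence

__all__ = [
    "AccumulatedImage",
    "accumulate",
    "empirical_snr",
    "accumulate_with_registration",
    "valid_center_crop",
    "compare_report",
]


@dataclass
class AccumulatedImage:
    """Pixelwise sum of a frame stack plus bookkeeping."""

    sum_pixels: np.ndarray
    frame_count: int
    provenance: str = "direct"  # "direct" | "registered"

    @property
    def mean(self) -> np.ndarray:
        """Mean-normalised view (sum / m), used for metrics and export."""
        return self.sum_pixels / self.frame_count

    def to_uint8(self) -> np.ndarray:
        """8-bit export: mean-normalise, round-half-even, clip to [0, 255]."""
        return np.clip(np.rint(self.mean), 0, 255).astype(np.uint8)


def accumulate(frames, provenance: str = "direct") -> AccumulatedImage:
    """Element-wise sum of >= 1 identically shaped frames, no clipping."""
    frames = [as_image(f) for f in frames]
    if not frames:
        raise ValueError("need at least 1 frame")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frame shape mismatch: {shapes}")
    total = np.zeros_like(frames[0])
    for f in frames:
        total += f
    return AccumulatedImage(total, len(frames), provenance)


def empirical_snr(signal_level: float, frames, signal_image=None) -> float:
    """SNR of the mean-normalised accumulation: signal level / residual-noise SD.

    The residual is the mean accumulation minus the known signal (a constant
    ``signal_level``, or a supplied ground-truth ``signal_image``).  For a
    single noisy frame with noise sigma this returns ~ signal_level / sigma;
    for m i.i.d. frames the value rises by ~ sqrt(m).
    """
    acc = accumulate(frames)
    reference = (
        float(signal_level) if signal_image is None else as_image(signal_image)
    )
    residual = acc.mean - reference
    noise_sd = float(np.std(residual))
    if noise_sd == 0.0:
        raise ValueError("zero residual-noise estimate; SNR undefined")
    return float(signal_level) / noise_sd


def valid_center_crop(mask: np.ndarray) -> tuple[slice, slice]:
    """Largest centered square-margin crop whose pixels are all valid.

    Shrinks a uniform margin from every side until the remaining window of the
    boolean ``mask`` is entirely True.  Raises if nothing valid remains.
    """
    m, n = mask.shape
    max_margin = min(m, n) // 2 - 1
    for s in range(0, max_margin + 1):
        window = mask[s : m - s, s : n - s]
        if window.size and window.all():
            return slice(s, m - s), slice(s, n - s)
    raise ValueError("no fully valid centered window in mask")


def accumulate_with_registration(
    frames,
    ga_cfg=None,
    cpso_cfg=None,
    bounds=None,
    *,
    method: str = "ga-cpso",
    levels: int = 256,
    downsample: int = 1,
):
    """Register all frames to the first, accumulate, and report quality.

    Returns ``(registered_acc, direct_acc, report, results)`` where the report
    is a :func:`compare_report` table of the five quality metrics (EOG,
    Brenner, gray level, SD, entropy) for the direct and the
    registered-then-accumulated image, both evaluated on the common valid
    crop.
    """
    frames = [as_image(f) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    results: list[RegistrationResult] = register_sequence(
        frames, ga_cfg, cpso_cfg, bounds, method=method, downsample=downsample
    )
    registered_acc = accumulate([r.registered for r in results], provenance="registered")
    direct_acc = accumulate(frames, provenance="direct")

    mask = np.ones(frames[0].shape, dtype=bool)
    for r in results[1:]:
        mask &= transform_valid_mask(frames[0].shape, r.transform)
    rows, cols = valid_center_crop(mask)

    report = compare_report(direct_acc, registered_acc, crop=(rows, cols), levels=levels)
    return registered_acc, direct_acc, report, results


def compare_report(
    direct: AccumulatedImage,
    registered: AccumulatedImage,
    crop: tuple[slice, slice] | None = None,
    levels: int = 256,
) -> pd.DataFrame:
    """One row per quality metric with direct, registered and fold-change values."""
    if direct.sum_pixels.shape != registered.sum_pixels.shape:
        raise ValueError("shape mismatch between accumulations")
    d_img = direct.mean
    r_img = registered.mean
    if crop is not None:
        rows, cols = crop
        d_img = d_img[rows, cols]
        r_img = r_img[rows, cols]
    d = quality_metrics(d_img, levels=levels)
    r = quality_metrics(r_img, levels=levels)
    records = []
    for name in d:
        fold = r[name] / d[name] if d[name] != 0 else np.inf
        records.append(
            {"metric": name, "direct": d[name], "registered": r[name], "fold_change": fold}
        )
    return pd.DataFrame(records, columns=["metric", "direct", "registered", "fold_change"])
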