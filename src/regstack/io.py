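"""Frame-stack reading and writing: PNG/TIFF files, numbered stacks, multi-page TIFF.

Frame order comes from natural-sorted numbered filenames or multi-page TIFF
page order; an ambiguous ordering (duplicate sort keys) is rejected rather
than guessed.  Video decoding (MP4/MOV) is optional and degrades gracefully
when the ffmpeg plugin is unavailable.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .imaging import as_image, to_grayscale

__all__ = [
    "natural_sort_key",
    "read_frames",
    "write_frames",
    "read_image",
    "write_image",
    "extract_video_frames",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


def natural_sort_key(name: str):
    """Sort key treating digit runs numerically ('frame10' after 'frame2')."""
    return tuple(
        int(tok) if tok.isdigit() else tok.lower()
        for tok in re.split(r"(\d+)", name)
    )


def _maybe_gray(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        return to_grayscale(arr)
    return as_image(arr)


def read_image(path) -> np.ndarray:
    """Read one PNG/TIFF image as a float grayscale Image2D (RGB averaged)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[0] > 1 and arr.shape[-1] not in (3, 4):
            raise ValueError(f"{path} is a multi-page TIFF; use read_frames")
    else:
        arr = iio.imread(path)
    return _maybe_gray(arr)


def write_image(path, img) -> None:
    """Write an image; float data is rounded/clipped to 8 bit for PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(img, dtype=np.float32))
    else:
        data = np.clip(np.rint(np.asarray(img, dtype=float)), 0, 255).astype(np.uint8)
        iio.imwrite(path, data)


def read_frames(source) -> list[np.ndarray]:
    """Read an ordered frame stack.

    ``source`` may be a directory of numbered PNG/TIFF frames, a multi-page
    TIFF file, or a single image (returned as a 1-frame list).
    """
    source = Path(source)
    if source.is_dir():
        files = [p for p in source.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES]
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {source}")
        keys = [natural_sort_key(p.name) for p in files]
        if len(set(keys)) != len(keys):
            raise ValueError(f"ambiguous frame ordering in {source}")
        ordered = [p for _, p in sorted(zip(keys, files))]
        return [read_image(p) for p in ordered]
    if source.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(source)
        if arr.ndim == 2:
            return [as_image(np.asarray(arr, dtype=float))]
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):
            return [_maybe_gray(arr)]
        return [_maybe_gray(page) for page in arr]
    return [read_image(source)]


def write_frames(directory, frames, prefix: str = "frame", fmt: str = "png") -> list[Path]:
    """Write frames as numbered images; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(frames))))
    paths = []
    for k, frame in enumerate(frames):
        p = directory / f"{prefix}_{k:0{width}d}.{fmt}"
        write_image(p, frame)
        paths.append(p)
    return paths


def extract_video_frames(video_path, out_dir, max_frames: int | None = None) -> list[Path]:
    """Extract video frames to numbered PNGs (requires the imageio ffmpeg plugin)."""
    try:
        frames = []
        for k, frame in enumerate(iio.imiter(video_path)):
            if max_frames is not None and k >= max_frames:
                break
            frames.append(_maybe_gray(frame))
    except Exception as exc:  # plugin missing or unreadable container
        raise RuntimeError(
            f"cannot decode {video_path!s}: video support needs the imageio "
            f"ffmpeg plugin ({exc})"
        ) from exc
    return write_frames(out_dir, frames)
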