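"""Synthetic transmission-phantom generator with known rigid motion.

Real low-SNR transmission frames of tissue are not redistributable, so every
experiment in this package runs on a synthetic stand-in: a smooth bright
blob (soft sigmoid edge) on a dark background — mimicking diffuse light
transmitted through a thick scattering sample — plus a few high-contrast
fiducial bars and a disc so that sharpness metrics (EOG, Brenner, MMD)
respond strongly to misalignment and ghosting.  Frames are rigidly displaced
copies of the base image with independent additive Gaussian noise (an
optional signal-dependent shot term is available but off by default), clipped
to the 8-bit intensity range.

Ground-truth transforms are retained, making the phantom the test bed for
parameter-recovery and accumulation-quality experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import RigidTransform, apply_rigid_transform, as_image

__all__ = [
    "Fiducial",
    "PhantomSpec",
    "PhantomSequence",
    "make_base_phantom",
    "make_sequence",
    "jitter_model",
]


@dataclass(frozen=True)
class Fiducial:
    """High-contrast marker added on top of the blob.

    ``kind`` is "bar" (axis-aligned rectangle) or "disc".  ``center`` is the
    (x, y) offset in pixels from the image center; ``size`` is (width, height)
    for bars or (radius, unused) for discs; ``amplitude`` is added to the
    underlying intensity (negative = dark marker).  Edges are softened over
    ~1 px so the registration cost surface stays smooth.
    """

    kind: str
    center: tuple[float, float]
    size: tuple[float, float]
    amplitude: float
    softness: float = 1.0


def _default_fiducials() -> tuple[Fiducial, ...]:
    return (
        Fiducial("bar", center=(-12.0, -8.0), size=(22.0, 4.0), amplitude=-45.0),
        Fiducial("bar", center=(8.0, 10.0), size=(4.0, 18.0), amplitude=-45.0),
        Fiducial("disc", center=(14.0, -10.0), size=(4.0, 0.0), amplitude=70.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise model of the synthetic sequence.

    Defaults give a 256x256 frame with background 20, a radius-31 blob of
    peak amplitude 120 above background (soft edge ~3 px) slightly off
    center, smooth interior texture, three fiducials, and additive Gaussian
    noise sigma 5 on the 0-255 scale — a low-contrast, moderately noisy
    transmission-like frame whose content keeps enough margin for rigid
    shifts up to +/-80 px.
    """

    shape: tuple[int, int] = (256, 256)
    background: float = 20.0
    blob_center: tuple[float, float] = (4.0, -3.0)  # (x, y) offset from image center
    blob_radius: float = 31.0
    blob_peak: float = 120.0
    edge_softness: float = 3.0
    texture_amplitude: float = 12.0  # smooth interior texture, mimics tissue structure
    texture_wavelength: float = 12.0  # px; band-limited so misalignment averages it away
    fiducials: tuple[Fiducial, ...] = field(default_factory=_default_fiducials)
    noise_sigma: float = 5.0
    shot_noise_frac: float = 0.0  # optional signal-dependent noise, off by default
    enforce_margin: bool = True  # reject transforms that push content out of frame
    rng_seed: int = 0

    def __post_init__(self) -> None:
        m, n = self.shape
        if m < 8 or n < 8:
            raise ValueError("phantom frame too small")
        if self.noise_sigma < 0 or self.shot_noise_frac < 0:
            raise ValueError("noise parameters must be >= 0")

    @classmethod
    def scaled(cls, size: int, **overrides) -> "PhantomSpec":
        """Compact default geometry scaled proportionally to a size x size frame."""
        f = size / 256.0
        base = cls()
        fids = tuple(
            Fiducial(
                fd.kind,
                (fd.center[0] * f, fd.center[1] * f),
                (fd.size[0] * f, fd.size[1] * f),
                fd.amplitude,
                max(1.0, fd.softness * f),
            )
            for fd in base.fiducials
        )
        params = dict(
            shape=(size, size),
            blob_center=(base.blob_center[0] * f, base.blob_center[1] * f),
            blob_radius=base.blob_radius * f,
            edge_softness=max(1.0, base.edge_softness * f),
            texture_wavelength=max(4.0, base.texture_wavelength * f),
            fiducials=fids,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def full_field(cls, **overrides) -> "PhantomSpec":
        """Variant whose object fills most of the frame, as acquired tissue does.

        Used for accumulation-quality studies, where the imaged sample covers
        the field of view and inter-frame motion is small.  The compact
        default keeps enough margin for the large-shift recovery scenarios
        instead.  Content may touch the frame edge, so the out-of-frame
        margin check is disabled (small motions clip a soft border, exactly
        as in real hand-held acquisitions).
        """
        overrides.setdefault("blob_radius", 90.0)
        overrides.setdefault("enforce_margin", False)
        return cls(**overrides)

    @property
    def content_radius(self) -> float:
        """Radius (from image center) enclosing all non-background content."""
        r = (
            float(np.hypot(*self.blob_center))
            + self.blob_radius
            + 3.0 * self.edge_softness
        )
        for f in self.fiducials:
            extent = max(f.size) / 2.0 + 3.0 * f.softness
            r = max(r, float(np.hypot(*f.center)) + extent)
        return r


@dataclass
class PhantomSequence:
    """Generated frames with their ground-truth transforms."""

    frames: list[np.ndarray]
    true_transforms: list[RigidTransform]
    spec: PhantomSpec


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_base_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic noise-free base image: blob plus fiducials."""
    m, n = spec.shape
    cy, cx = (m - 1) / 2.0, (n - 1) / 2.0
    if spec.enforce_margin and spec.content_radius > min(cx, cy):
        raise ValueError("phantom content exceeds the frame")
    x = np.arange(n, dtype=float)[None, :] - cx
    y = np.arange(m, dtype=float)[:, None] - cy

    bx, by = spec.blob_center
    r = np.hypot(x - bx, y - by)
    interior = _sigmoid((spec.blob_radius - r) / max(spec.edge_softness, 1e-6))
    img = spec.background + spec.blob_peak * interior

    if spec.texture_amplitude > 0:
        # deterministic band-limited texture confined to the blob interior;
        # ghosting from misaligned accumulation averages it away, mimicking
        # the texture loss real tissue images suffer without registration
        k = 2.0 * np.pi / spec.texture_wavelength
        tex = (
            np.sin(k * (x - bx)) * np.sin(k * 0.83 * (y - by))
            + 0.6 * np.sin(k * 0.57 * (x - bx) + 1.1) * np.sin(k * 1.21 * (y - by) + 0.4)
        )
        img = img + spec.texture_amplitude * tex * interior

    for f in spec.fiducials:
        fx, fy = f.center
        if f.kind == "bar":
            w, h = f.size
            px = _sigmoid((w / 2.0 - np.abs(x - fx)) / f.softness)
            py = _sigmoid((h / 2.0 - np.abs(y - fy)) / f.softness)
            img = img + f.amplitude * px * py
        elif f.kind == "disc":
            radius = f.size[0]
            rr = np.hypot(x - fx, y - fy)
            img = img + f.amplitude * _sigmoid((radius - rr) / f.softness)
        else:
            raise ValueError(f"unknown fiducial kind {f.kind!r}")

    return as_image(np.clip(img, 0.0, 255.0))


def _check_margins(spec: PhantomSpec, transforms) -> None:
    if not spec.enforce_margin:
        return
    m, n = spec.shape
    cy, cx = (m - 1) / 2.0, (n - 1) / 2.0
    r = spec.content_radius
    for t in transforms:
        if abs(t.tx) > cx - r or abs(t.ty) > cy - r:
            raise ValueError(
                f"transform {t} pushes phantom content (radius {r:.1f}) out of frame"
            )


def make_sequence(spec: PhantomSpec, transforms) -> PhantomSequence:
    """Transformed, independently noised copies of the base phantom.

    Frame k is ``clip(warp(base, transforms[k]) + noise_k, 0, 255)``; each
    frame's noise stream is split deterministically from the spec-level seed.
    """
    transforms = list(transforms)
    if not transforms:
        raise ValueError("need at least one transform")
    _check_margins(spec, transforms)
    base = make_base_phantom(spec)
    streams = np.random.SeedSequence(spec.rng_seed).spawn(len(transforms))
    frames = []
    for t, ss in zip(transforms, streams):
        frame = base if t.is_identity else apply_rigid_transform(base, t)
        rng = np.random.default_rng(ss)
        noisy = frame.copy()
        if spec.noise_sigma > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_sigma, size=frame.shape)
        if spec.shot_noise_frac > 0:
            noisy = noisy + rng.normal(0.0, 1.0, size=frame.shape) * (
                spec.shot_noise_frac * np.sqrt(np.clip(frame, 0.0, None))
            )
        if spec.noise_sigma > 0 or spec.shot_noise_frac > 0:
            noisy = np.clip(noisy, 0.0, 255.0)
        frames.append(as_image(noisy))
    return PhantomSequence(frames, transforms, spec)


def jitter_model(
    n_frames: int,
    translation_sigma: float,
    rotation_sigma: float,
    seed: int = 0,
) -> list[RigidTransform]:
    """Zero-mean Gaussian per-frame rigid jitter; frame 0 forced to identity.

    Models small camera shake / respiratory motion between consecutive
    frames: translations ~ N(0, translation_sigma^2) px per axis, rotation
    ~ N(0, rotation_sigma^2) degrees.
    """
    if translation_sigma < 0 or rotation_sigma < 0:
        raise ValueError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    out = [RigidTransform()]
    for _ in range(n_frames - 1):
        tx, ty = rng.normal(0.0, translation_sigma, size=2)
        th = rng.normal(0.0, rotation_sigma)
        out.append(RigidTransform(float(tx), float(ty), float(th)))
    return out
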