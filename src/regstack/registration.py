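"""Pairwise and fixed-reference multi-frame rigid registration.

The registration objective is the mean squared error between the fixed image
and the rigidly warped moving image, minimised by the GA-CPSO hybrid.  The
search starts conceptually from the zero transform (tx = ty = theta = 0): the
zero-transform cost is recorded as ``initial_cost`` and acts as a guard rail —
if the optimiser somehow returns something worse, the identity transform is
kept, so ``final_cost <= initial_cost`` always holds.

Multi-frame sequences are registered against a single fixed reference (the
first frame) rather than chained pairwise, which avoids compounding
superposition errors across the sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._warp import warp_mse
from .imaging import RigidTransform, apply_rigid_transform, as_image
from .optimizers import (
    CPSOConfig,
    GAConfig,
    HybridResult,
    SearchBounds,
    cpso_phase,
    ga_cpso,
)

__all__ = ["RegistrationResult", "make_mse_cost", "register_pair", "register_sequence"]


@dataclass
class RegistrationResult:
    """Estimated transform, costs and traces for one fixed/moving pair."""

    transform: RigidTransform
    final_cost: float
    initial_cost: float
    result: HybridResult | None  # optimiser traces; None for the fixed reference frame
    registered: np.ndarray


def make_mse_cost(fixed, moving, downsample: int = 1):
    """Build the MSE cost closure over rigid-transform space.

    ``downsample`` > 1 evaluates the cost on a decimated grid (every k-th
    pixel) with translations rescaled accordingly — an optional speed knob,
    disabled by default.
    """
    fixed = as_image(fixed)
    moving = as_image(moving)
    if fixed.shape != moving.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    k = int(downsample)
    if k > 1:
        fixed = np.ascontiguousarray(fixed[::k, ::k])
        moving = np.ascontiguousarray(moving[::k, ::k])

    def cost(t: RigidTransform) -> float:
        th = math.radians(t.theta)
        return float(
            warp_mse(fixed, moving, math.cos(th), math.sin(th), t.tx / k, t.ty / k)
        )

    return cost


def register_pair(
    fixed,
    moving,
    ga_cfg: GAConfig | None = None,
    cpso_cfg: CPSOConfig | None = None,
    bounds: SearchBounds | None = None,
    *,
    downsample: int = 1,
    method: str = "ga-cpso",
) -> RegistrationResult:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    ``method`` is "ga-cpso" (default hybrid) or "cpso" (stand-alone swarm with
    uniform random initialisation, the baseline the hybrid is compared
    against).
    """
    fixed = as_image(fixed)
    moving = as_image(moving)
    if fixed.shape != moving.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    ga_cfg = ga_cfg or GAConfig()
    cpso_cfg = cpso_cfg or CPSOConfig()
    bounds = bounds or SearchBounds()

    cost = make_mse_cost(fixed, moving, downsample=downsample)
    initial_cost = cost(RigidTransform())

    if method == "ga-cpso":
        result = ga_cpso(cost, bounds, ga_cfg, cpso_cfg)
    elif method == "cpso":
        swarm = cpso_phase(cost, bounds, cpso_cfg, init_center=None)
        result = HybridResult(swarm.position, swarm.cost, ga=swarm, cpso=swarm)
    else:
        raise ValueError(f"unknown method {method!r}")

    if result.cost <= initial_cost:
        transform, final_cost = result.position, result.cost
    else:
        transform, final_cost = RigidTransform(), initial_cost

    registered = apply_rigid_transform(moving, transform)
    return RegistrationResult(transform, final_cost, initial_cost, result, registered)


def register_sequence(
    frames,
    ga_cfg: GAConfig | None = None,
    cpso_cfg: CPSOConfig | None = None,
    bounds: SearchBounds | None = None,
    *,
    downsample: int = 1,
    method: str = "ga-cpso",
) -> list[RegistrationResult]:
    """Register every frame of a sequence to the first frame (fixed reference).

    Frame 0 gets an identity result; each later frame is registered to frame 0
    independently, with per-frame RNG seeds derived from the configs' base
    seeds so the whole sequence is reproducible yet frames are not correlated.
    """
    frames = [as_image(f) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frame shape mismatch: {shapes}")
    ga_cfg = ga_cfg or GAConfig()
    cpso_cfg = cpso_cfg or CPSOConfig()
    bounds = bounds or SearchBounds()

    fixed = frames[0]
    results = [
        RegistrationResult(RigidTransform(), 0.0, 0.0, None, fixed.copy())
    ]
    for k, frame in enumerate(frames[1:], start=1):
        ga_k = replace(ga_cfg, rng_seed=int(ga_cfg.rng_seed) + 10_000 * k)
        cpso_k = replace(cpso_cfg, rng_seed=int(cpso_cfg.rng_seed) + 10_000 * k)
        results.append(
            register_pair(
                fixed,
                frame,
                ga_k,
                cpso_k,
                bounds,
                downsample=downsample,
                method=method,
            )
        )
    return results
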