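"""Linear interpolation baseline reconstructor.

For equally spaced dense slices, target k of 2m-1 sits at fraction
k/(2m) of the way from the left to the right bounding slice, so the
natural linear estimate is the voxelwise convex combination at those
fractions. Exact whenever intensity is affine in slice index; on real
anatomy (or the nonlinear phantom) moving boundaries make it ghost,
which is the regime a learned reconstructor targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FractionSchedule", "fraction_schedule", "linear_interpolate",
           "reconstruct_linear"]


@dataclass(frozen=True)
class FractionSchedule:
    """The 2m-1 interpolation weights k/(2m), strictly increasing in (0, 1)."""

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions)
        if f.size == 0 or np.any(f <= 0) or np.any(f >= 1) or np.any(np.diff(f) <= 0):
            raise ValueError(f"fractions must be strictly increasing in (0,1): {self.fractions}")


def fraction_schedule(targets_per_gap: int) -> FractionSchedule:
    step = targets_per_gap + 1  # = 2m
    return FractionSchedule(tuple(k / step for k in range(1, step)))


def linear_interpolate(left: np.ndarray, right: np.ndarray, fraction: float) -> np.ndarray:
    """Voxelwise (1 - fraction) * left + fraction * right."""
    left = np.asarray(left, dtype=np.float64)
    right = np.asarray(right, dtype=np.float64)
    if left.shape != right.shape:
        raise ValueError(f"slice shapes differ: {left.shape} vs {right.shape}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    return ((1.0 - fraction) * left + fraction * right).astype(np.float32)


def reconstruct_linear(sparse_stack: np.ndarray, targets_per_gap: int) -> list[np.ndarray]:
    """Per-gap stacks of linearly interpolated targets for every neighbor pair."""
    from .slicing import neighbor_pairs

    schedule = fraction_schedule(targets_per_gap)
    return [
        np.stack([linear_interpolate(left, right, f) for f in schedule.fractions])
        for left, right in neighbor_pairs(np.asarray(sparse_stack))
    ]
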