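"""Sparse/target slice grouping and merging of reconstructed slices.

A dense stack of n slices S_1..S_n is separated into a sparse subset
(every 2m-th slice, starting at S_1) and the target slices strictly
between consecutive sparse slices. Each gap holds exactly 2m-1 targets;
the reconstructor predicts those targets from the gap's two bounding
slices, and :func:`merge_reconstruction` reassembles a dense stack by
copying the sparse originals through unchanged and filling the gaps with
predictions. Trailing slices that do not complete a final gap take part
in neither group and are reported as excluded.

The half-gap parameter m may be a multiple of 0.5 (m = 1.5 means 2
targets per gap); the API works in integer ``targets_per_gap = 2m - 1``
throughout and keeps m only for reporting. All user-facing indices are
1-based to match the usual S_t slice notation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .volume_io import NormalizedVolume

__all__ = ["SliceGrouping", "make_grouping", "split_volume", "neighbor_pairs",
           "merge_reconstruction"]

#: targets-per-gap values covered by the evaluation protocol (m = 1 .. 3)
SUPPORTED_TARGETS_PER_GAP = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class SliceGrouping:
    """Index bookkeeping for one (n_dense, m) combination; 1-based indices."""

    m: float
    targets_per_gap: int
    n_dense: int
    sparse_indices: tuple[int, ...]
    gaps: tuple[tuple[int, int, tuple[int, ...]], ...]
    excluded: tuple[int, ...]

    @property
    def step(self) -> int:
        """Index step between consecutive sparse slices (= 2m)."""
        return self.targets_per_gap + 1

    @property
    def target_indices(self) -> tuple[int, ...]:
        return tuple(t for _, _, targets in self.gaps for t in targets)

    @property
    def n_used(self) -> int:
        return self.sparse_indices[-1]

    def to_json(self) -> str:
        return json.dumps({
            "m": self.m,
            "targets_per_gap": self.targets_per_gap,
            "n_dense": self.n_dense,
            "sparse_indices": list(self.sparse_indices),
            "excluded": list(self.excluded),
        })


def make_grouping(n_dense: int, targets_per_gap: int) -> SliceGrouping:
    """Build the sparse/target grouping for a dense stack of ``n_dense`` slices.

    ``targets_per_gap`` is 2m - 1: the number of slices reconstructed
    between each pair of retained slices. Sparse indices run 1, 1+2m,
    1+4m, ...; any dense slices after the last full gap are excluded.
    """
    if targets_per_gap < 1:
        raise ValueError("targets_per_gap must be >= 1")
    if targets_per_gap not in SUPPORTED_TARGETS_PER_GAP:
        warnings.warn(
            f"targets_per_gap={targets_per_gap} is outside the evaluated range "
            f"{SUPPORTED_TARGETS_PER_GAP}", stacklevel=2)
    step = targets_per_gap + 1
    if n_dense < step + 1:
        raise ValueError(
            f"n_dense={n_dense} too small for targets_per_gap={targets_per_gap}; "
            f"need at least {step + 1} dense slices")
    sparse = tuple(range(1, n_dense + 1, step))
    if len(sparse) < 2:  # unreachable given the check above, kept for safety
        raise ValueError("grouping needs at least two sparse slices")
    gaps = tuple(
        (left, right, tuple(range(left + 1, right)))
        for left, right in zip(sparse[:-1], sparse[1:])
    )
    excluded = tuple(range(sparse[-1] + 1, n_dense + 1))
    return SliceGrouping(m=step / 2.0, targets_per_gap=targets_per_gap,
                         n_dense=n_dense, sparse_indices=sparse, gaps=gaps,
                         excluded=excluded)


def _as_stack(vol) -> np.ndarray:
    if isinstance(vol, NormalizedVolume):
        return vol.voxels
    return np.asarray(vol)


def split_volume(vol, grouping: SliceGrouping) -> tuple[np.ndarray, np.ndarray]:
    """Extract (sparse stack, target stack) from a dense volume.

    Accepts a :class:`NormalizedVolume` or a raw ``(z, y, x)`` array.
    Returns arrays of shape ``(K, H, W)`` and ``(K-1, 2m-1, H, W)`` where
    K is the sparse-slice count; targets are grouped per gap in order.
    """
    stack = _as_stack(vol)
    if stack.shape[0] < grouping.n_used:
        raise IndexError(
            f"volume has {stack.shape[0]} slices, grouping needs {grouping.n_used}")
    sparse = stack[[i - 1 for i in grouping.sparse_indices]]
    targets = np.stack([
        stack[[t - 1 for t in targets]]
        for _, _, targets in grouping.gaps
    ])
    return sparse, targets


def neighbor_pairs(sparse_stack: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Consecutive (left, right) slice pairs; one per gap."""
    sparse_stack = np.asarray(sparse_stack)
    if sparse_stack.shape[0] < 2:
        raise ValueError("need at least 2 sparse slices to form a pair")
    return [(sparse_stack[i], sparse_stack[i + 1])
            for i in range(sparse_stack.shape[0] - 1)]


def merge_reconstruction(sparse_stack: np.ndarray,
                         per_gap_stacks,
                         grouping: SliceGrouping) -> np.ndarray:
    """Interleave sparse originals with reconstructed gap stacks.

    ``per_gap_stacks`` holds one ``(2m-1, H, W)`` array per gap. The output
    has ``K + (K-1)(2m-1)`` slices; the originals are copied bit-for-bit
    into the sparse positions (the method never re-synthesizes a measured
    slice).
    """
    sparse_stack = np.asarray(sparse_stack)
    per_gap_stacks = [np.asarray(s) for s in per_gap_stacks]
    K = sparse_stack.shape[0]
    if len(per_gap_stacks) != K - 1:
        raise ValueError(f"expected {K - 1} gap stacks, got {len(per_gap_stacks)}")
    for s in per_gap_stacks:
        if s.shape[0] != grouping.targets_per_gap or s.shape[1:] != sparse_stack.shape[1:]:
            raise ValueError(
                f"gap stack shape {s.shape} incompatible with sparse slices "
                f"{sparse_stack.shape} and targets_per_gap={grouping.targets_per_gap}")
    out = np.empty((grouping.n_used,) + sparse_stack.shape[1:], dtype=sparse_stack.dtype)
    for k, idx in enumerate(grouping.sparse_indices):
        out[idx - 1] = sparse_stack[k]
    for gap_stack, (_, _, targets) in zip(per_gap_stacks, grouping.gaps):
        for j, t in enumerate(targets):
            out[t - 1] = gap_stack[j]
    return out
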