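"""Organ range-clip transform: estimate, apply, invert.

For a single organ the CT values occupy a much narrower band of the
normalized [0, 1] intensity scale than the whole slice does. The
range-clip transform stretches that band to the full unit interval:

    f(x) = 0            if x < R_ll
           1            if x > R_lh
           B (x - C)    if R_ll <= x <= R_lh

with C = R_ll and B = 1/(R_lh - R_ll), the unique affine map taking
[R_ll, R_lh] onto [0, 1]. Training a reconstructor on f-transformed
volumes concentrates its capacity on the organ's intensity band; at test
time f is applied to the inputs and f^-1 to the outputs. f is lossy
outside the organ band (everything below R_ll collapses to 0), which is
why organ-oriented merging keeps a base network for the rest of the
image.

The band is estimated from labeled training volumes with percentile
trimming, which plays the role of manual removal of outlier intensities
(surgical staples, drainage tubes). Gas pockets in the stomach sit near
the air end of the scale and would wreck its band, so an air mask
excludes them from estimation and replacement.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from .volume_io import NormalizedVolume, LabelVolume

__all__ = ["RangeClipParams", "REFERENCE_ABDOMINAL_PARAMS", "estimate_range",
           "fit_params", "apply_f", "apply_f_inverse", "air_mask",
           "save_params", "load_params"]

#: default air threshold on the normalized scale: 0.25 = -500 HU under the
#: fixed [-1000, 1000] HU window
DEFAULT_AIR_THRESHOLD = 0.25


@dataclass(frozen=True)
class RangeClipParams:
    """Per-organ constants of the transform: band [r_ll, r_lh], offset c, gain b."""

    organ: str
    r_ll: float
    r_lh: float
    c: float
    b: float

    def __post_init__(self):
        if not (0.0 <= self.r_ll <= self.r_lh <= 1.0):
            raise ValueError(f"band must satisfy 0 <= R_ll <= R_lh <= 1, got "
                             f"[{self.r_ll}, {self.r_lh}]")
        if self.b <= 0:
            raise ValueError("gain B must be positive")
        if abs(self.b * (self.r_lh - self.c) - 1.0) > 1e-9 or abs(self.c - self.r_ll) > 1e-9:
            raise ValueError("params must map [R_ll, R_lh] onto [0, 1]")

    @classmethod
    def from_constants(cls, organ: str, c: float, b: float) -> "RangeClipParams":
        """Build from published (C, B) constants; the band is (C, C + 1/B)."""
        return cls(organ=organ, r_ll=c, r_lh=c + 1.0 / b, c=c, b=b)


#: (C, B) constants reported for a 130-patient abdominal CT cohort under the
#: fixed [-1000, 1000] HU window; loadable verbatim as an alternative to
#: fitting on one's own training data.
REFERENCE_ABDOMINAL_PARAMS = {
    "liver": RangeClipParams.from_constants("liver", 0.400, 4.545),
    "left_kidney": RangeClipParams.from_constants("left_kidney", 0.418, 4.762),
    "right_kidney": RangeClipParams.from_constants("right_kidney", 0.440, 6.250),
    "stomach": RangeClipParams.from_constants("stomach", 0.320, 4.000),
}


def estimate_range(volumes, labels, organ, trim: tuple[float, float] = (0.5, 99.5),
                   exclude_air_below: float | None = None) -> tuple[float, float]:
    """Trimmed empirical intensity band of an organ, pooled over volumes.

    ``organ`` is a label code or organ name. ``trim`` gives lower/upper
    percentiles; (0, 100) is the raw min/max. ``exclude_air_below`` drops
    voxels under the given normalized value first (used for the stomach).
    The result is invariant to the order of the input volumes.
    """
    lo_pct, hi_pct = trim
    if not (0 <= lo_pct <= hi_pct <= 100):
        raise ValueError(f"bad trim percentiles {trim}")
    pooled = []
    for vol, lab in zip(volumes, labels, strict=True):
        voxels = vol.voxels if isinstance(vol, NormalizedVolume) else np.asarray(vol)
        mask = lab.mask(organ) if isinstance(lab, LabelVolume) else np.asarray(lab, bool)
        values = voxels[mask]
        if exclude_air_below is not None:
            values = values[values >= exclude_air_below]
        if values.size:
            pooled.append(values)
    if not pooled:
        raise ValueError(f"no voxels labeled {organ!r} in the supplied volumes")
    values = np.concatenate(pooled)
    return (float(np.percentile(values, lo_pct)),
            float(np.percentile(values, hi_pct)))


def fit_params(r_ll: float, r_lh: float, organ: str = "organ") -> RangeClipParams:
    """C = R_ll and B = 1/(R_lh - R_ll): f(R_ll) = 0 and f(R_lh) = 1."""
    if not r_lh > r_ll:
        raise ValueError(f"band width must be positive, got [{r_ll}, {r_lh}]")
    return RangeClipParams(organ=organ, r_ll=float(r_ll), r_lh=float(r_lh),
                           c=float(r_ll), b=1.0 / (r_lh - r_ll))


def _apply_f_array(x: np.ndarray, p: RangeClipParams) -> np.ndarray:
    x = np.asarray(x)
    out_dtype = x.dtype if np.issubdtype(x.dtype, np.floating) else np.float64
    xe = x.astype(np.float64)
    out = p.b * (xe - p.c)
    out = np.where(xe < p.r_ll, 0.0, out)
    out = np.where(xe > p.r_lh, 1.0, out)
    return np.clip(out, 0.0, 1.0).astype(out_dtype)


def apply_f(vol, p: RangeClipParams):
    """Voxelwise range-clip transform; accepts a NormalizedVolume or array."""
    if isinstance(vol, NormalizedVolume):
        return NormalizedVolume(
            voxels=_apply_f_array(vol.voxels.astype(np.float64), p).astype(np.float32),
            window=vol.window, spacing=vol.spacing)
    return _apply_f_array(vol, p)


def apply_f_inverse(vol, p: RangeClipParams):
    """y -> y/B + C; inverts f on the organ band [R_ll, R_lh].

    Outside the band f is a clamp and information is lost: f^-1(f(x))
    returns R_ll (resp. R_lh) for x below (above) the band.
    """
    if isinstance(vol, NormalizedVolume):
        y = vol.voxels.astype(np.float64)
        return NormalizedVolume(voxels=(y / p.b + p.c).astype(np.float32),
                                window=vol.window, spacing=vol.spacing)
    y = np.asarray(vol)
    out_dtype = y.dtype if np.issubdtype(y.dtype, np.floating) else np.float64
    return (y.astype(np.float64) / p.b + p.c).astype(out_dtype)


def air_mask(vol, threshold: float = DEFAULT_AIR_THRESHOLD) -> np.ndarray:
    """Boolean mask of air-like voxels (below ``threshold`` on [0, 1])."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    voxels = vol.voxels if isinstance(vol, NormalizedVolume) else np.asarray(vol)
    return voxels < threshold


def save_params(params: dict[str, RangeClipParams], path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        json.dump({organ: asdict(p) for organ, p in params.items()}, fh, indent=2)


def load_params(path: str | os.PathLike) -> dict[str, RangeClipParams]:
    with open(os.fspath(path)) as fh:
        raw = json.load(fh)
    return {organ: RangeClipParams(**d) for organ, d in raw.items()}
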