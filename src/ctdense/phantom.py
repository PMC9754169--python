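"""Synthetic labeled CT-like phantoms with nonlinear through-plane structure.

Each phantom is a normalized [0, 1] volume plus an aligned label mask,
emulating the statistical features the reconstruction method relies on
in anisotropic abdominal CT: a smooth wide-range background, several
compact "organ" regions whose intensities occupy narrow sub-bands of the
scale (the premise of the range-clip transform), organ cross-sections
that drift and pulse *nonlinearly* along the longitudinal axis (so
linear slice interpolation ghosts at boundaries, the regime where a
learned reconstructor can win), and an optional near-zero air pocket
inside the stomach region labeled as stomach (so the air filter has work
to do).

Default organ intensity bands are the reference abdominal bands (liver
0.40-0.62, kidneys ~0.42-0.63 / 0.44-0.60, stomach 0.32-0.57 on the
[-1000, 1000] HU window). An ``affine`` motion mode generates static
organs with intensities affine in slice index, on which linear
interpolation is exact — the analytic oracle for the baseline.

No anatomy or CT physics is simulated; geometry is ellipsoids and
low-frequency fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume_io import NormalizedVolume, LabelVolume, DEFAULT_ORGAN_MAP

__all__ = ["OrganSpec", "PhantomConfig", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class OrganSpec:
    """One ellipsoidal organ: intensity band plus center/radius paths.

    Positions and radii are fractions of the in-plane image extent.
    ``drift_amp`` is the amplitude of the sinusoidal in-plane drift of the
    center along z; ``radius_pulse`` the relative radius modulation.
    """

    code: int
    name: str
    intensity_range: tuple[float, float]
    center: tuple[float, float]            # (y, x) at z = 0, fractional
    radii: tuple[float, float]             # (ry, rx), fractional
    drift_amp: tuple[float, float] = (0.06, 0.08)
    drift_freq: float = 0.9                # cycles over the full z extent
    phase: tuple[float, float] = (0.0, 1.6)
    radius_pulse: float = 0.2
    radius_freq: float = 0.7
    radius_phase: float = 0.5


def _default_organs() -> list[OrganSpec]:
    return [
        OrganSpec(1, "liver", (0.400, 0.620), center=(0.38, 0.37),
                  radii=(0.17, 0.20), drift_amp=(0.05, 0.05)),
        OrganSpec(2, "left_kidney", (0.418, 0.628), center=(0.74, 0.28),
                  radii=(0.10, 0.11), drift_amp=(0.05, 0.05), phase=(0.8, 2.4)),
        OrganSpec(3, "right_kidney", (0.440, 0.600), center=(0.74, 0.72),
                  radii=(0.10, 0.11), drift_amp=(0.05, 0.05), phase=(2.1, 0.4)),
        OrganSpec(4, "stomach", (0.320, 0.570), center=(0.33, 0.68),
                  radii=(0.13, 0.14), drift_amp=(0.05, 0.05), phase=(1.2, 3.0)),
    ]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one phantom volume."""

    shape: tuple[int, int, int] = (25, 64, 64)      # (z, y, x)
    organs: list[OrganSpec] = field(default_factory=_default_organs)
    background_range: tuple[float, float] = (0.05, 0.75)
    air_pocket_organ: int | None = 4                # organ code, None disables
    air_pocket_radius_frac: float = 0.45
    air_pocket_intensity: float = 0.02
    noise_sd: float = 0.01
    motion: str = "nonlinear"                       # or "affine"
    seed: int = 0
    spacing: tuple[float, float, float] = (2.5, 1.0742, 1.0742)

    def __post_init__(self):
        if self.motion not in ("nonlinear", "affine"):
            raise ValueError(f"unknown motion mode {self.motion!r}")
        blo, bhi = self.background_range
        for o in self.organs:
            lo, hi = o.intensity_range
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"organ {o.name}: bad intensity range {o.intensity_range}")
            if hi - lo >= bhi - blo:
                raise ValueError(
                    f"organ {o.name}: band {o.intensity_range} must be narrower "
                    f"than the background range {self.background_range}")


def _smooth_field(rng: np.random.Generator, shape, n_modes: int = 4) -> np.ndarray:
    """Low-frequency random field in [0, 1] (sum of 3-D cosine modes)."""
    nz, ny, nx = shape
    z = np.linspace(0, 1, nz)[:, None, None]
    y = np.linspace(0, 1, ny)[None, :, None]
    x = np.linspace(0, 1, nx)[None, None, :]
    out = np.zeros(shape)
    for _ in range(n_modes):
        fz, fy, fx = rng.uniform(0.3, 1.6, 3)
        ph = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        out += amp * np.cos(2 * np.pi * (fz * z + fy * y + fx * x) + ph)
    out -= out.min()
    ptp = out.max()
    return out / ptp if ptp > 0 else out


def _organ_paths(o: OrganSpec, zbar: np.ndarray, motion: str):
    """Center (cy, cx) and radii (ry, rx) as functions of normalized z."""
    if motion == "affine":
        ones = np.ones_like(zbar)
        return (o.center[0] * ones, o.center[1] * ones,
                o.radii[0] * ones, o.radii[1] * ones)
    cy = o.center[0] + o.drift_amp[0] * np.sin(2 * np.pi * o.drift_freq * zbar + o.phase[0])
    cx = o.center[1] + o.drift_amp[1] * np.sin(2 * np.pi * o.drift_freq * zbar + o.phase[1])
    pulse = 1.0 + o.radius_pulse * np.sin(2 * np.pi * o.radius_freq * zbar + o.radius_phase)
    return cy, cx, o.radii[0] * pulse, o.radii[1] * pulse


def generate_phantom(cfg: PhantomConfig, seed: int | None = None
                     ) -> tuple[NormalizedVolume, LabelVolume]:
    """Deterministically generate one (volume, labels) pair from cfg.seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    nz, ny, nx = cfg.shape
    zbar = np.linspace(0, 1, nz)
    yy = np.linspace(0, 1, ny)[:, None]
    xx = np.linspace(0, 1, nx)[None, :]

    blo, bhi = cfg.background_range
    if cfg.motion == "affine":
        base2d = _smooth_field(rng, (1, ny, nx))[0]
        slope = rng.uniform(0.1, 0.25)
        vol = blo + (bhi - blo - slope) * base2d[None] + slope * zbar[:, None, None]
    else:
        vol = blo + (bhi - blo) * _smooth_field(rng, cfg.shape)
    labels = np.zeros(cfg.shape, dtype=np.int16)

    for o in cfg.organs:
        cy, cx, ry, rx = _organ_paths(o, zbar, cfg.motion)
        if (np.any(cy - ry < 0) or np.any(cy + ry > 1)
                or np.any(cx - rx < 0) or np.any(cx + rx > 1)):
            raise ValueError(f"organ {o.name}: ellipsoid path leaves the grid")
        lo, hi = o.intensity_range
        if cfg.motion == "affine":
            tex2d = _smooth_field(rng, (1, ny, nx))[0]
            oslope = rng.uniform(0.05, 0.15) * (hi - lo)
            texture = (lo + (hi - lo - oslope) * tex2d[None]
                       + oslope * zbar[:, None, None])
        else:
            texture = lo + (hi - lo) * _smooth_field(rng, cfg.shape)
        for iz in range(nz):
            inside = (((yy - cy[iz]) / ry[iz]) ** 2
                      + ((xx - cx[iz]) / rx[iz]) ** 2) <= 1.0
            vol[iz][inside] = texture[iz][inside]
            labels[iz][inside] = o.code

        if cfg.air_pocket_organ == o.code:
            frac = cfg.air_pocket_radius_frac
            for iz in range(nz):
                pocket = (((yy - cy[iz]) / (ry[iz] * frac)) ** 2
                          + ((xx - cx[iz]) / (rx[iz] * frac)) ** 2) <= 1.0
                vol[iz][pocket] = cfg.air_pocket_intensity
                # air stays labeled as its enclosing organ

    if cfg.noise_sd > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sd, cfg.shape)
    vol = np.clip(vol, 0.0, 1.0).astype(np.float32)
    organ_map = dict(DEFAULT_ORGAN_MAP)
    for o in cfg.organs:
        organ_map[o.code] = o.name
    return (NormalizedVolume(voxels=vol, spacing=cfg.spacing),
            LabelVolume(codes=labels, organ_map=organ_map))


def _jitter_organ(o: OrganSpec, rng: np.random.Generator) -> OrganSpec:
    lo, hi = o.intensity_range
    shift = rng.uniform(-0.005, 0.005)
    return replace(
        o,
        intensity_range=(lo + shift, hi + shift),
        center=(o.center[0] + rng.uniform(-0.02, 0.02),
                o.center[1] + rng.uniform(-0.02, 0.02)),
        radii=(o.radii[0] * rng.uniform(0.9, 1.1),
               o.radii[1] * rng.uniform(0.9, 1.1)),
        drift_amp=(o.drift_amp[0] * rng.uniform(0.8, 1.2),
                   o.drift_amp[1] * rng.uniform(0.8, 1.2)),
        phase=(rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi)),
        radius_phase=rng.uniform(0, 2 * np.pi),
    )


def generate_dataset(cfg: PhantomConfig, n_volumes: int = 30,
                     split: tuple[float, float] = (0.8, 0.2),
                     master_seed: int = 0):
    """A cohort of jittered phantoms with a disjoint volume-level split.

    Each volume gets its own seeded jitter of organ positions, drift
    phases/amplitudes and intensity-band shifts, emulating inter-patient
    variation. Returns (train, test) lists of (volume, labels) pairs;
    the 80/20 default matches the standard evaluation split.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes to split")
    if not np.isclose(sum(split), 1.0) or min(split) <= 0:
        raise ValueError(f"degenerate split {split}")
    master = np.random.SeedSequence(master_seed)
    vol_seeds = master.generate_state(n_volumes + 1)
    volumes = []
    for i in range(n_volumes):
        jrng = np.random.default_rng(vol_seeds[i])
        vcfg = replace(cfg, organs=[_jitter_organ(o, jrng) for o in cfg.organs],
                       seed=int(vol_seeds[i] % (2 ** 31)))
        volumes.append(generate_phantom(vcfg))
    n_train = int(round(split[0] * n_volumes))
    n_train = min(max(n_train, 1), n_volumes - 1)
    order = np.random.default_rng(vol_seeds[-1]).permutation(n_volumes)
    train = [volumes[i] for i in sorted(order[:n_train])]
    test = [volumes[i] for i in sorted(order[n_train:])]
    return train, test
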