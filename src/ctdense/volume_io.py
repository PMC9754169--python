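"""Volume containers and I/O: NIfTI/DICOM reading, HU windowing, normalization.

CT intensities live on the Hounsfield scale (air ~ -1000 HU, water 0 HU).
All learning and range-clip computation happens in a normalized [0, 1]
domain obtained by clipping to a fixed HU window and mapping it affinely
onto the unit interval. The window is fixed (default [-1000, 1000] HU)
rather than per-volume, so that training and test volumes share one
intensity domain; values outside it (dense bone, metal) are clamped.

Volumes are stored slice-major ``(z, y, x)`` with the longitudinal
(through-plane) axis first; slice indices are 0-based in code and 1-based
in user-facing reports.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib
import pydicom

__all__ = [
    "CTVolume",
    "NormalizedVolume",
    "LabelVolume",
    "DEFAULT_HU_WINDOW",
    "DEFAULT_ORGAN_MAP",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "clip_hu",
    "normalize",
    "denormalize",
]

DEFAULT_HU_WINDOW = (-1000.0, 1000.0)

#: organ label codes used throughout (0 is always background)
DEFAULT_ORGAN_MAP = {
    0: "background",
    1: "liver",
    2: "left_kidney",
    3: "right_kidney",
    4: "stomach",
}


@dataclass
class CTVolume:
    """A 3-D CT grid in Hounsfield units.

    Parameters
    ----------
    voxels:
        ``(z, y, x)`` float array of HU values; the longitudinal axis is
        axis 0.
    spacing:
        ``(dz, dy, dx)`` voxel spacing in millimetres, all strictly
        positive. Abdominal protocols are typically anisotropic, e.g.
        2.5 mm between slices versus ~1.07 mm in-plane.
    slice_axis:
        Index of the longitudinal axis. Volumes are canonicalized to
        ``slice_axis == 0`` on read; the field exists so a caller can
        assert or override the orientation.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (2.5, 1.0742, 1.0742)
    slice_axis: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.voxels.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if self.voxels.shape[self.slice_axis] < 2:
            raise ValueError("volume needs at least 2 slices along the longitudinal axis")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[self.slice_axis]


@dataclass
class NormalizedVolume:
    """A volume mapped into [0, 1]; ``window`` records the HU window used."""

    voxels: np.ndarray
    window: tuple[float, float] = DEFAULT_HU_WINDOW
    spacing: tuple[float, float, float] = (2.5, 1.0742, 1.0742)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        lo = float(self.voxels.min(initial=0.0))
        hi = float(self.voxels.max(initial=0.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"normalized voxels outside [0, 1]: min={lo}, max={hi}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class LabelVolume:
    """Integer organ codes aligned voxel-for-voxel with a CT grid."""

    codes: np.ndarray
    organ_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_ORGAN_MAP))

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("label codes must be integers")
        present = set(np.unique(self.codes).tolist())
        unknown = present - set(self.organ_map)
        if unknown:
            raise ValueError(f"label codes {sorted(unknown)} missing from organ_map")

    def mask(self, organ: int | str) -> np.ndarray:
        """Boolean mask for an organ given by code or name."""
        code = organ if isinstance(organ, int) else self.code_of(organ)
        return self.codes == code

    def code_of(self, name: str) -> int:
        for code, organ in self.organ_map.items():
            if organ == name:
                return code
        raise KeyError(f"organ {name!r} not in organ_map")


# ---------------------------------------------------------------------------
# reading / writing


def _canonical_from_nifti(img: "nib.Nifti1Image", slice_axis: int | None):
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI, got shape {data.shape}")
    axis = int(np.argmax(zooms)) if slice_axis is None else slice_axis
    data = np.moveaxis(data, axis, 0)
    spacing = (float(zooms[axis]),) + tuple(float(z) for i, z in enumerate(zooms) if i != axis)
    return data, spacing


def read_volume(path: str | os.PathLike, *, slice_axis: int | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    The longitudinal axis is taken from ``slice_axis`` if given, otherwise
    it defaults to the axis with the largest voxel spacing (the
    reconstruction axis in anisotropic acquisitions). The returned volume
    is canonicalized so that axis is axis 0.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.isdir(path):
        return _read_dicom_series(path)
    data, spacing = _canonical_from_nifti(nib.load(path), slice_axis)
    return CTVolume(voxels=data.astype(np.float32), spacing=spacing)


def _read_dicom_series(dirname: str, spacing_tol: float = 1e-3) -> CTVolume:
    """Assemble a DICOM series; inter-slice distance comes from slice positions.

    The slice increment (distance between consecutive ImagePositionPatient
    z-coordinates) can legitimately differ from SliceThickness when the
    acquisition leaves gaps; the increment is what matters for
    reconstruction, so it defines ``spacing[0]``.
    """
    files = sorted(
        os.path.join(dirname, f) for f in os.listdir(dirname) if not f.startswith(".")
    )
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except pydicom.errors.InvalidDicomError:
            continue
    if len(datasets) < 2:
        raise ValueError(f"need at least 2 DICOM slices in {dirname}")
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    zs = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
    steps = np.diff(zs)
    if np.ptp(steps) > spacing_tol:
        raise ValueError(f"inconsistent DICOM slice spacing: steps {steps}")
    dz = float(steps.mean())
    dy, dx = (float(v) for v in datasets[0].PixelSpacing)
    slope = float(getattr(datasets[0], "RescaleSlope", 1.0))
    intercept = float(getattr(datasets[0], "RescaleIntercept", 0.0))
    stack = np.stack([d.pixel_array.astype(np.float32) for d in datasets])
    return CTVolume(voxels=stack * slope + intercept, spacing=(dz, dy, dx))


def write_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI; voxel spacing goes into the affine diagonal."""
    dz, dy, dx = vol.spacing
    affine = np.diag([dz, dy, dx, 1.0])
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), os.fspath(path))


def read_labels(path: str | os.PathLike, organ_map: dict[int, str] | None = None,
                *, slice_axis: int | None = None) -> LabelVolume:
    data, _ = _canonical_from_nifti(nib.load(os.fspath(path)), slice_axis)
    return LabelVolume(codes=np.rint(data).astype(np.int16),
                       organ_map=dict(organ_map or DEFAULT_ORGAN_MAP))


def write_labels(labels: LabelVolume, path: str | os.PathLike,
                 spacing: tuple[float, float, float] = (2.5, 1.0742, 1.0742)) -> None:
    dz, dy, dx = spacing
    affine = np.diag([dz, dy, dx, 1.0])
    nib.save(nib.Nifti1Image(labels.codes.astype(np.int16), affine), os.fspath(path))


# ---------------------------------------------------------------------------
# HU window / normalization


def clip_hu(vol: CTVolume, lo: float = DEFAULT_HU_WINDOW[0],
            hi: float = DEFAULT_HU_WINDOW[1]) -> CTVolume:
    """Clamp voxel values to the HU window [lo, hi]. Idempotent."""
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got [{lo}, {hi}]")
    return replace(vol, voxels=np.clip(vol.voxels, lo, hi))


def normalize(vol: CTVolume, lo: float = DEFAULT_HU_WINDOW[0],
              hi: float = DEFAULT_HU_WINDOW[1]) -> NormalizedVolume:
    """Map an already-clipped volume affinely from [lo, hi] HU onto [0, 1]."""
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got [{lo}, {hi}]")
    v = vol.voxels
    if v.min() < lo - 1e-6 or v.max() > hi + 1e-6:
        raise ValueError(
            f"volume not clipped to [{lo}, {hi}]: range [{v.min()}, {v.max()}]; "
            "call clip_hu first"
        )
    out = (np.clip(v, lo, hi) - lo) / (hi - lo)
    return NormalizedVolume(voxels=out.astype(np.float32), window=(lo, hi),
                            spacing=vol.spacing)


def denormalize(vol: NormalizedVolume) -> CTVolume:
    """Inverse of :func:`normalize` using the recorded window."""
    lo, hi = vol.window
    return CTVolume(voxels=(vol.voxels * (hi - lo) + lo).astype(np.float32),
                    spacing=vol.spacing)
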