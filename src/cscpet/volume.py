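"""SUV volume data model and NIfTI I/O.

FDG uptake is quantified as the standardized uptake value (SUV): tissue
activity concentration normalized by the injected dose per body weight,

    SUV = activity [kBq/mL] * body_weight [kg] / injected_dose [MBq]

which is dimensionless (conventionally g/mL).  All downstream volumetric
parameters (MTV, TLG and their cluster-restricted variants) are computed on a
:class:`SUVVolume`: a 3-D voxel grid of SUVs with its physical spacing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "SUVVolume",
    "InjectionRecord",
    "VolumeError",
    "read_volume",
    "write_volume",
    "suv_from_activity",
]


class VolumeError(ValueError):
    """Raised for malformed volumes, headers or injection records."""


@dataclass(frozen=True)
class SUVVolume:
    """A 3-D grid of SUV values with physical voxel spacing.

    Parameters
    ----------
    data
        3-D array of SUV values; must be finite and non-negative.
    spacing
        Voxel edge lengths in mm per axis; must be positive.  Anisotropic
        spacing is permitted; all volumetric math uses the voxel volume.
    origin
        Physical offset of the first voxel in mm (informational).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise VolumeError(f"expected a 3-D volume, got {data.ndim}-D data")
        if data.size == 0:
            raise VolumeError("volume must have at least one voxel per axis")
        if not np.all(np.isfinite(data)):
            raise VolumeError("SUV values must be finite")
        if np.any(data < 0):
            raise VolumeError("SUV values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3:
            raise VolumeError("spacing must have three components")
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise VolumeError(f"voxel spacing must be positive, got {spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in cm^3 (product of mm spacings / 1000)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def suv_max(self) -> float:
        return float(self.data.max())


@dataclass(frozen=True)
class InjectionRecord:
    """Quantities needed for body-weight SUV normalization.

    ``uptake_time`` (minutes post injection) is carried for provenance only;
    no decay correction is applied here.
    """

    injected_dose: float  # MBq
    body_weight: float  # kg
    uptake_time: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not np.isfinite(self.injected_dose) or self.injected_dose <= 0:
            raise VolumeError(f"injected dose must be > 0 MBq, got {self.injected_dose}")
        if not np.isfinite(self.body_weight) or self.body_weight <= 0:
            raise VolumeError(f"body weight must be > 0 kg, got {self.body_weight}")


def read_volume(path: str | os.PathLike) -> SUVVolume:
    """Read a 3-D NIfTI volume of SUV values.

    Spacing is taken from the header ``pixdim`` fields; values are passed
    through unchanged.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) != 3:
        raise VolumeError(
            f"expected a 3-D image, got a {len(shape)}-D image of shape {shape}"
        )
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise VolumeError(f"non-positive voxel spacing in header: {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return SUVVolume(data=data, spacing=zooms, origin=origin)


def write_volume(vol: SUVVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine built from spacing."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def suv_from_activity(
    activity: np.ndarray,
    spacing: tuple[float, float, float],
    injection: InjectionRecord,
) -> SUVVolume:
    """Convert an activity-concentration volume (kBq/mL) to SUV.

    Uses the body-weight normalization SUV = A * W / D with A in kBq/mL,
    W in kg and D in MBq (the kBq/MBq and mL/g factors cancel for unit tissue
    density).  Linear in activity and inversely proportional to dose.
    """
    activity = np.asarray(activity, dtype=np.float64)
    if np.any(activity < 0):
        raise VolumeError("activity concentrations must be non-negative")
    suv = activity * (injection.body_weight / injection.injected_dose)
    return SUVVolume(data=suv, spacing=spacing)
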