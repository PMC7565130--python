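"""Lesion VOI definition by SUV thresholding.

Lesions are delineated on the SUV grid as 26-connected components of voxels
at or above a threshold: a fixed absolute threshold of SUV 2.5 for MTV/TLG
and the novel CSC parameters, and a relative threshold of 40% of SUVmax for
the MTV40%/TLG40% variants.  Tumors with SUVmax < 2.5 are FDG non-avid and
are excluded from analysis.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import SUVVolume

__all__ = [
    "LesionVOI",
    "SegmentationError",
    "segment_fixed_threshold",
    "segment_relative_threshold",
    "check_avidity",
    "AVIDITY_THRESHOLD",
]

AVIDITY_THRESHOLD = 2.5

#: full 3x3x3 neighborhood -> 26-connectivity
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class LesionVOI:
    """A lesion volume of interest: voxel indices with their SUVs.

    ``indices`` are 0-based grid coordinates, one row per voxel, stored in
    C (lexicographic) order; ``suv`` is aligned 1:1 with them.
    """

    indices: np.ndarray  # (n, 3) int
    suv: np.ndarray  # (n,) float
    voxel_volume: float  # cm^3
    label: str = "lesion"
    threshold: float | None = field(default=None)

    def __post_init__(self) -> None:
        indices = np.atleast_2d(np.asarray(self.indices, dtype=np.intp))
        suv = np.asarray(self.suv, dtype=np.float64).ravel()
        if indices.shape[0] == 0:
            raise SegmentationError("VOI must contain at least one voxel")
        if indices.shape[1] != 3:
            raise SegmentationError("VOI indices must be 3-tuples")
        if indices.shape[0] != suv.shape[0]:
            raise SegmentationError(
                f"{indices.shape[0]} indices but {suv.shape[0]} SUV values"
            )
        if len({tuple(row) for row in indices.tolist()}) != indices.shape[0]:
            raise SegmentationError("VOI voxel indices must be unique")
        if self.voxel_volume <= 0:
            raise SegmentationError("voxel volume must be positive")
        if self.threshold is not None and np.any(suv < self.threshold - 1e-12):
            raise SegmentationError("VOI contains SUVs below its threshold")
        object.__setattr__(self, "indices", indices)
        object.__setattr__(self, "suv", suv)

    def __len__(self) -> int:
        return int(self.indices.shape[0])

    @property
    def suv_max(self) -> float:
        return float(self.suv.max())

    @property
    def hottest_index(self) -> tuple[int, int, int]:
        """Index of the hottest voxel; lexicographic tie-break for determinism."""
        peak = self.suv.max()
        cand = self.indices[self.suv == peak]
        order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
        return tuple(int(v) for v in cand[order[0]])

    def to_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[tuple(self.indices.T)] = True
        return mask

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "label": self.label,
            "voxel_volume_cm3": self.voxel_volume,
            "threshold": self.threshold,
            "indices": self.indices.tolist(),
            "suv": self.suv.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "LesionVOI":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            indices=np.asarray(payload["indices"], dtype=np.intp),
            suv=np.asarray(payload["suv"], dtype=np.float64),
            voxel_volume=float(payload["voxel_volume_cm3"]),
            label=payload.get("label", "lesion"),
            threshold=payload.get("threshold"),
        )


def _component_voi(
    vol: SUVVolume,
    threshold: float,
    anchor: tuple[int, int, int],
    label: str,
) -> LesionVOI:
    mask = vol.data >= threshold
    labeled, _ = ndimage.label(mask, structure=_STRUCT26)
    component = labeled == labeled[anchor]
    indices = np.argwhere(component)
    return LesionVOI(
        indices=indices,
        suv=vol.data[component],
        voxel_volume=vol.voxel_volume,
        label=label,
        threshold=threshold,
    )


def _check_seed(vol: SUVVolume, seed) -> tuple[int, int, int]:
    seed = tuple(int(i) for i in seed)
    if len(seed) != 3:
        raise SegmentationError("seed must be a 3-tuple of voxel indices")
    for ax, (i, n) in enumerate(zip(seed, vol.data.shape)):
        if not 0 <= i < n:
            raise SegmentationError(
                f"seed index {i} out of bounds for axis {ax} of size {n}"
            )
    return seed


def segment_fixed_threshold(
    vol: SUVVolume,
    seed: tuple[int, int, int],
    threshold: float = AVIDITY_THRESHOLD,
    label: str = "lesion",
) -> LesionVOI:
    """26-connected component of voxels with SUV >= ``threshold`` at ``seed``.

    The comparison is inclusive: the threshold value itself belongs to the
    lesion.  The seed voxel must itself be avid at the threshold.
    """
    seed = _check_seed(vol, seed)
    if vol.data[seed] < threshold:
        raise SegmentationError(
            f"seed not avid: SUV {vol.data[seed]:.3f} at {seed} is below "
            f"threshold {threshold}"
        )
    return _component_voi(vol, threshold, seed, label)


def segment_relative_threshold(
    vol: SUVVolume,
    base_voi: LesionVOI,
    fraction: float = 0.40,
) -> LesionVOI:
    """Component at ``fraction`` * SUVmax, anchored at the base VOI's peak.

    SUVmax is taken within ``base_voi`` (the fixed-threshold lesion); the
    returned VOI is the 26-connected component of voxels at or above
    fraction*SUVmax that contains the base VOI's hottest voxel.
    """
    if not 0 < fraction < 1:
        raise SegmentationError(f"fraction must lie in (0, 1), got {fraction}")
    peak = base_voi.hottest_index
    threshold = fraction * base_voi.suv_max
    return _component_voi(vol, threshold, peak, f"{base_voi.label}@{fraction:.0%}SUVmax")


def check_avidity(obj: SUVVolume | LesionVOI, threshold: float = AVIDITY_THRESHOLD) -> bool:
    """True iff SUVmax >= 2.5 (inclusive); non-avid cases are excluded upstream."""
    return float(obj.suv_max) >= threshold
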