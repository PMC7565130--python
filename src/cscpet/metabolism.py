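"""Per-lesion metabolic parameters: conventional and CSC-restricted.

Conventional parameters on the SUV-2.5 lesion VOI:

* SUVmax — maximum voxel SUV,
* MTV (cm^3) — voxel count x voxel volume,
* TLG (SUV*cm^3) — summed voxel SUVs x voxel volume (= mean SUV x MTV),

plus MTV40%/TLG40% on the 40%-of-SUVmax VOI.  The novel CSC parameters
restrict MTV and TLG to the most glycolytic (highest-centroid) cluster of
the K=3 SUV partition:

* MTVcsc, TLGcsc — volume and glycolysis of the top cluster,
* CSC proportion (%) — 100 x MTVcsc / MTV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import ClusterPartition
from .segmentation import LesionVOI

__all__ = [
    "CSCParameters",
    "ConventionalParameters",
    "csc_parameters",
    "conventional_parameters",
    "patient_level_mtvcsc",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CSCParameters:
    mtv_csc: float  # cm^3
    tlg_csc: float  # SUV*cm^3
    csc_proportion: float  # percent of MTV

    def __post_init__(self) -> None:
        if self.mtv_csc <= 0 or self.tlg_csc <= 0:
            raise ValueError("CSC volume and glycolysis must be positive")
        if not 0 < self.csc_proportion <= 100:
            raise ValueError(
                f"CSC proportion must lie in (0, 100], got {self.csc_proportion}"
            )


@dataclass(frozen=True)
class ConventionalParameters:
    suv_max: float
    mtv: float  # cm^3
    tlg: float  # SUV*cm^3
    mtv40: float  # cm^3
    tlg40: float  # SUV*cm^3


def csc_parameters(voi: LesionVOI, partition: ClusterPartition) -> CSCParameters:
    """CSC parameters from the most glycolytic cluster of ``partition``.

    The partition must have been computed on this VOI (1:1 voxel alignment).
    """
    if partition.labels.shape[0] != len(voi):
        raise ValueError(
            f"partition covers {partition.labels.shape[0]} voxels but VOI has "
            f"{len(voi)}"
        )
    top = partition.labels == partition.k - 1
    vv = voi.voxel_volume
    mtv_csc = float(top.sum()) * vv
    tlg_csc = float(voi.suv[top].sum()) * vv
    mtv = float(len(voi)) * vv
    return CSCParameters(
        mtv_csc=mtv_csc,
        tlg_csc=tlg_csc,
        csc_proportion=100.0 * mtv_csc / mtv,
    )


def conventional_parameters(voi: LesionVOI, voi40: LesionVOI) -> ConventionalParameters:
    """SUVmax, MTV, TLG on ``voi`` and MTV40%/TLG40% on ``voi40``."""
    if not np.isclose(voi.voxel_volume, voi40.voxel_volume):
        raise ValueError("VOIs must share the same voxel volume")
    vv = voi.voxel_volume
    return ConventionalParameters(
        suv_max=voi.suv_max,
        mtv=float(len(voi)) * vv,
        tlg=float(voi.suv.sum()) * vv,
        mtv40=float(len(voi40)) * vv,
        tlg40=float(voi40.suv.sum()) * vv,
    )


def patient_level_mtvcsc(lesions: Sequence[tuple[str, CSCParameters]]) -> float:
    """Patient-level MTVcsc: the maximum across the patient's lesions.

    Primary tumors usually carry the largest CSC volume, but a nodal maximum
    is allowed; the contributing lesion's label is logged.
    """
    if not lesions:
        raise ValueError("patient has no lesions")
    label, best = max(lesions, key=lambda item: item[1].mtv_csc)
    logger.info("patient-level MTVcsc %.3f cm^3 from lesion %r", best.mtv_csc, label)
    return best.mtv_csc
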