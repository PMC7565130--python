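"""Published summary counts of the reference neoadjuvant breast-cancer cohort.

The 120-patient cohort this package's defaults are calibrated to reported
its response and covariate data only as summary tables.  Those printed cell
counts are shipped here as example inputs so the contingency statistics and
cutoff-accuracy tabulations can be recomputed end to end without patient-
level data.  Rows are exposure levels, columns are (pCR, residual tumor).
"""

from __future__ import annotations

import numpy as np

from .classify import ConfusionTable
from .cohort import ContingencyTable2x2

__all__ = [
    "pcr_univariable_tables",
    "response_confusion_tables",
    "nac_regimen_response_table",
    "dual_her2_response_table",
    "accuracy_by_subtype_table",
    "accuracy_by_anti_her2_table",
]


def pcr_univariable_tables() -> dict[str, ContingencyTable2x2]:
    """2x2 tables (exposure rows x pCR/residual columns) for the univariable
    odds ratios in the HER2-positive/triple-negative cohort (n=82; grade and
    Ki-67 rows have missing cases and smaller denominators)."""
    return {
        # exposure level of interest first, reference level second
        "t_stage_1_2": ContingencyTable2x2(a=20, b=33, c=2, d=27),
        "stage_IIA_IIIA": ContingencyTable2x2(a=20, b=46, c=2, d=14),
        "grade_3": ContingencyTable2x2(a=11, b=28, c=8, d=30),
        "ki67_high": ContingencyTable2x2(a=9, b=35, c=8, d=25),
        "er_negative": ContingencyTable2x2(a=18, b=37, c=4, d=23),
    }


def response_confusion_tables() -> dict[str, ConfusionTable]:
    """MTVcsc < 1.75 cm^3 confusion tables by subtype and NAC regimen."""
    return {
        "her2_tn": ConfusionTable(a=22, b=21, c=0, d=39),
        "luminal": ConfusionTable(a=0, b=27, c=0, d=11),
        "anthracycline_taxane": ConfusionTable(a=16, b=14, c=0, d=27),
        "taxane": ConfusionTable(a=6, b=5, c=0, d=7),
        "anthracycline": ConfusionTable(a=0, b=2, c=0, d=5),
        "anti_her2_nac": ConfusionTable(a=12, b=5, c=0, d=14),
        "no_anti_her2_nac": ConfusionTable(a=4, b=13, c=0, d=9),
    }


def nac_regimen_response_table() -> np.ndarray:
    """pCR/residual counts by NAC regimen (anthracycline+taxane, taxane,
    anthracycline) in the HER2-positive/TN cohort; a 2x3 table for Fisher."""
    return np.array([[16, 6, 0], [41, 12, 7]])


def dual_her2_response_table() -> np.ndarray:
    """pCR/residual by dual vs single/no HER2 blockade among 57 HER2-positive
    patients (rows: dual inhibition, not dual)."""
    return np.array([[10, 12], [6, 29]])


def accuracy_by_subtype_table() -> np.ndarray:
    """Correct/incorrect cutoff predictions, HER2-positive/TN vs luminal."""
    return np.array([[61, 21], [11, 27]])


def accuracy_by_anti_her2_table() -> np.ndarray:
    """Correct/incorrect cutoff predictions, with vs without neoadjuvant
    anti-HER2 therapy among HER2-positive patients."""
    return np.array([[26, 5], [13, 13]])
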