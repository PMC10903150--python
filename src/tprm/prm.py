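"""Voxel-wise parametric response mapping (PRM) of paired lung CT.

Each lung voxel of a co-registered inspiration/expiration HU pair is
classified by joint density thresholds into normal parenchyma (Norm),
functional small airways disease (fSAD), emphysema (Emph) or parenchymal
disease (PD).  Voxels outside the analysable HU range, threshold-boundary
voxels, and indeterminate voxels are left Unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CLASS_CODES",
    "CODE_NAMES",
    "PairedCT",
    "PRMMap",
    "classify_voxels",
    "percent_volume",
    "qc_flag",
    "lung_air_volumes_l",
]

# Canonical integer label codes shared by every writer in the package.
CLASS_CODES: dict[str, int] = {
    "Norm": 1,
    "fSAD": 2,
    "Emph": 3,
    "PD": 4,
    "Unclassified": 5,
}
CODE_NAMES: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}

# HU thresholds of the PRM scheme.
HU_RANGE = (-1000.0, -250.0)   # analysable range, both scans, inclusive
INSP_EMPH = -950.0             # Emph: insp < -950; Norm/fSAD: -950 < insp <= -810
INSP_PD = -810.0               # PD: insp > -810
EXP_TRAP = -856.0              # air trapping: exp < -856; Norm: exp >= -856


@dataclass
class PairedCT:
    """Aligned inspiration/expiration HU volumes with a lung mask.

    Both volumes live on the expiratory geometric frame; registration and
    lung/airway segmentation are upstream preconditions, not performed here.
    """

    insp_hu: np.ndarray
    exp_hu: np.ndarray
    lung_mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.65, 0.65, 0.65)

    def __post_init__(self):
        self.insp_hu = np.asarray(self.insp_hu)
        self.exp_hu = np.asarray(self.exp_hu)
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        if not (self.insp_hu.shape == self.exp_hu.shape == self.lung_mask.shape):
            raise ValueError(
                "inspiration, expiration and mask volumes must share shape: "
                f"{self.insp_hu.shape}, {self.exp_hu.shape}, {self.lung_mask.shape}"
            )
        if self.insp_hu.ndim != 3:
            raise ValueError("volumes must be 3D")
        if not self.lung_mask.any():
            raise ValueError("lung mask is empty")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class PRMMap:
    """Per-voxel PRM class labels and percent-volume summary.

    ``labels`` uses :data:`CLASS_CODES` inside the lung mask and 0 outside.
    """

    labels: np.ndarray
    percent_volume: dict[str, float]


def classify_voxels(ct: PairedCT) -> PRMMap:
    """Classify every lung voxel by its joint (insp, exp) HU pair.

    The printed threshold inequalities are honoured literally:

    * Norm: -950 < insp <= -810 and exp >= -856
    * fSAD: -950 < insp <= -810 and exp <  -856
    * Emph: insp < -950 and exp < -856
    * PD:   insp > -810

    Voxels with either scan outside [-1000, -250] HU, indeterminate voxels
    (insp < -950 with exp > -856) and unreachable boundary combinations
    (e.g. insp exactly -950) are Unclassified.
    """
    insp = ct.insp_hu
    exp = ct.exp_hu
    mask = ct.lung_mask

    labels = np.zeros(mask.shape, dtype=np.uint8)
    in_range = (
        (insp >= HU_RANGE[0]) & (insp <= HU_RANGE[1])
        & (exp >= HU_RANGE[0]) & (exp <= HU_RANGE[1])
    )
    norm_insp = (insp > INSP_EMPH) & (insp <= INSP_PD)
    labels[mask & in_range & norm_insp & (exp >= EXP_TRAP)] = CLASS_CODES["Norm"]
    labels[mask & in_range & norm_insp & (exp < EXP_TRAP)] = CLASS_CODES["fSAD"]
    labels[mask & in_range & (insp < INSP_EMPH) & (exp < EXP_TRAP)] = CLASS_CODES["Emph"]
    labels[mask & in_range & (insp > INSP_PD)] = CLASS_CODES["PD"]
    labels[mask & (labels == 0)] = CLASS_CODES["Unclassified"]

    prm = PRMMap(labels=labels, percent_volume={})
    prm.percent_volume = percent_volume(prm, mask)
    return prm


def percent_volume(prm: PRMMap, lung_mask: np.ndarray) -> dict[str, float]:
    """Percent of the expiratory lung volume occupied by each PRM class.

    Unclassified voxels are excluded from the numerators but remain in the
    denominator (the total lung volume at expiration).
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    total = int(lung_mask.sum())
    if total == 0:
        raise ValueError("lung mask is empty")
    inside = prm.labels[lung_mask]
    return {
        cls: 100.0 * float((inside == code).sum()) / total
        for cls, code in CLASS_CODES.items()
    }


def lung_air_volumes_l(ct: PairedCT) -> tuple[float, float]:
    """HU-derived lung air volume (L) at inspiration and expiration.

    Uses the standard density decomposition: a voxel at h HU holds an air
    fraction of ``-h/1000`` (air = -1000 HU, tissue/water = 0 HU).  With a
    single expiratory-frame mask this is the quantity that still responds
    to the respiratory phase of each scan.
    """
    mask = ct.lung_mask
    vox_l = ct.voxel_volume_mm3 / 1e6
    insp_frac = np.clip(-ct.insp_hu[mask] / 1000.0, 0.0, 1.0)
    exp_frac = np.clip(-ct.exp_hu[mask] / 1000.0, 0.0, 1.0)
    return float(insp_frac.sum() * vox_l), float(exp_frac.sum() * vox_l)


def qc_flag(
    ct: PairedCT,
    min_volume_l: float = 1.0,
    max_volume_l: float = 10.0,
) -> tuple[bool, str]:
    """Minimal quality-control surrogate for a paired scan.

    Fails when the expiratory air volume is not smaller than the
    inspiratory one (an erroneous volume change) or when either volume is
    physiologically implausible.  Returns ``(passed, reason)``.
    """
    insp_l, exp_l = lung_air_volumes_l(ct)
    if not (min_volume_l <= insp_l <= max_volume_l):
        return False, f"implausible inspiratory volume {insp_l:.2f} L"
    if not (min_volume_l <= exp_l <= max_volume_l):
        return False, f"implausible expiratory volume {exp_l:.2f} L"
    if exp_l >= insp_l:
        return False, (
            f"erroneous volume change: expiration {exp_l:.2f} L >= "
            f"inspiration {insp_l:.2f} L"
        )
    return True, "ok"
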