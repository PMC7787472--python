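"""Lesion mask processing and T1-hypointensity-derived axonal-loss estimation.

The lesion *core* is obtained by shrinking the lesion mask by one voxel
(morphological erosion); the peeled shell is the *rim*.  Axonal loss is
estimated linearly from T1 intensity between two anchors: normal-appearing
white matter (NAWM, intact tissue, f = 0) and CSF (tissue devoid of axons,
f = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import ScalarVolume

__all__ = [
    "LesionMaskSet",
    "AxonalLossEstimate",
    "SubsetComparison",
    "split_core_rim",
    "filter_lesions",
    "estimate_axonal_loss",
    "compare_voxel_subsets",
]

_STRUCTURES = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])


def split_core_rim(
    lesion_mask: np.ndarray, connectivity: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Split a binary lesion mask into a 1-voxel-eroded core and its rim.

    Erosion uses a 6-connected (faces-only) structuring element by default;
    18- and 26-connectivity are available.  A lesion thinner than 3 voxels
    in every direction erodes to an empty core (warned, not an error).
    """
    mask = np.asarray(lesion_mask).astype(bool)
    core = ndimage.binary_erosion(mask, structure=_structure(connectivity))
    rim = mask & ~core
    if mask.any() and not core.any():
        warnings.warn("lesion erodes to an empty core", stacklevel=2)
    return core, rim


@dataclass
class LesionMaskSet:
    """Labelled lesion grid with per-lesion core/rim masks and volumes.

    ``labels`` holds 0 for background and a positive integer id per lesion.
    """

    labels: np.ndarray
    affine: np.ndarray
    connectivity: int = 6
    _cores: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _rims: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("lesion labels must be a 3-D grid")
        self.affine = np.asarray(self.affine, dtype=float)

    @classmethod
    def from_binary(
        cls, mask: np.ndarray, affine: np.ndarray, connectivity: int = 6
    ) -> "LesionMaskSet":
        """Label connected components of a binary lesion mask (26-connected
        components, as is usual for lesion counting)."""
        labels, _ = ndimage.label(
            np.asarray(mask).astype(bool), structure=_structure(26)
        )
        return cls(labels=labels, affine=affine, connectivity=connectivity)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def ids(self) -> list[int]:
        return [int(i) for i in np.unique(self.labels) if i > 0]

    @property
    def volumes_mm3(self) -> dict[int, float]:
        return {
            i: float(np.count_nonzero(self.labels == i)) * self.voxel_volume_mm3
            for i in self.ids
        }

    @property
    def any_lesion(self) -> np.ndarray:
        return self.labels > 0

    def lesion_mask(self, lesion_id: int) -> np.ndarray:
        return self.labels == lesion_id

    def core_mask(self, lesion_id: int) -> np.ndarray:
        if lesion_id not in self._cores:
            core, rim = split_core_rim(self.lesion_mask(lesion_id), self.connectivity)
            self._cores[lesion_id], self._rims[lesion_id] = core, rim
        return self._cores[lesion_id]

    def rim_mask(self, lesion_id: int) -> np.ndarray:
        self.core_mask(lesion_id)
        return self._rims[lesion_id]

    def table(self) -> pd.DataFrame:
        vols = self.volumes_mm3
        return pd.DataFrame(
            {"lesion_id": list(vols), "volume_mm3": list(vols.values())}
        )


def filter_lesions(
    mask_set: LesionMaskSet, min_volume_mm3: float = 100.0
) -> LesionMaskSet:
    """Drop lesions not *strictly larger* than ``min_volume_mm3``.

    At 1 mm³ voxels the default keeps lesions of 101+ voxels: a 100-voxel
    lesion is not "larger than 100 mm³" and is removed.
    """
    labels = np.asarray(mask_set.labels).copy()
    for lesion_id, vol in mask_set.volumes_mm3.items():
        if not vol > min_volume_mm3:
            labels[labels == lesion_id] = 0
    return LesionMaskSet(
        labels=labels, affine=mask_set.affine, connectivity=mask_set.connectivity
    )


@dataclass
class AxonalLossEstimate:
    """T1-derived axonal-loss fractions.

    f is the linear position of the mean lesional T1 intensity between the
    NAWM mean (f = 0) and the CSF minimum (f = 1), clipped to [0, 1].
    """

    i_nawm: float
    i_csf_min: float
    f_per_lesion: dict[int, float]
    f_patient: float
    n_fiber_voxels: dict[int, int]
    weights: dict[int, float]
    excluded: list[int] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "lesion_id": k,
                "f": v,
                "f_percent": 100.0 * v,
                "n_fiber_voxels": self.n_fiber_voxels[k],
                "weight": self.weights[k],
            }
            for k, v in self.f_per_lesion.items()
        ]
        return pd.DataFrame(rows)


def _fraction(i_lesion: float, i_nawm: float, i_csf: float) -> float:
    return float(np.clip((i_nawm - i_lesion) / (i_nawm - i_csf), 0.0, 1.0))


def estimate_axonal_loss(
    t1: ScalarVolume,
    lesion_set: LesionMaskSet,
    fiber_voxel_mask: np.ndarray,
    nawm_rois: np.ndarray,
    csf_rois: np.ndarray,
    fiber_counts: dict[int, int] | None = None,
) -> AxonalLossEstimate:
    """Estimate per-lesion and patient-level axonal-loss fractions from T1.

    Only lesional voxels intersected by at least one lesional streamline
    (``fiber_voxel_mask``) enter the intensity average — voxels without
    traversing fibers are not part of the streamline analysis and tend to
    be more destructive.  The patient value is a weighted mean over
    lesions; weights are the lesional fiber counts when supplied,
    otherwise the number of analysed voxels.

    Lesions whose fiber-intersected voxel set is empty are excluded with a
    warning.
    """
    t1_data = np.asarray(t1.data, dtype=float)
    nawm_rois = np.asarray(nawm_rois, dtype=bool)
    csf_rois = np.asarray(csf_rois, dtype=bool)
    fiber_voxel_mask = np.asarray(fiber_voxel_mask, dtype=bool)
    if not nawm_rois.any() or not csf_rois.any():
        raise ValueError("NAWM and CSF reference ROIs must be non-empty")
    i_nawm = float(t1_data[nawm_rois].mean())
    i_csf = float(t1_data[csf_rois].min())
    if not i_nawm > i_csf:
        raise ValueError("NAWM mean intensity must exceed the CSF minimum")

    f_per_lesion: dict[int, float] = {}
    n_vox: dict[int, int] = {}
    excluded: list[int] = []
    for lesion_id in lesion_set.ids:
        vox = lesion_set.lesion_mask(lesion_id) & fiber_voxel_mask
        n = int(np.count_nonzero(vox))
        if n == 0:
            warnings.warn(
                f"lesion {lesion_id}: no fiber-intersected voxels, excluded",
                stacklevel=2,
            )
            excluded.append(lesion_id)
            continue
        f_per_lesion[lesion_id] = _fraction(float(t1_data[vox].mean()), i_nawm, i_csf)
        n_vox[lesion_id] = n

    if not f_per_lesion:
        raise ValueError("no lesion has fiber-intersected voxels")

    if fiber_counts is not None:
        raw = {k: float(fiber_counts.get(k, 0)) for k in f_per_lesion}
    else:
        raw = {k: float(n_vox[k]) for k in f_per_lesion}
    total = sum(raw.values())
    if total == 0:
        raw = {k: 1.0 for k in raw}
        total = float(len(raw))
    weights = {k: v / total for k, v in raw.items()}
    f_patient = float(sum(weights[k] * f_per_lesion[k] for k in f_per_lesion))
    return AxonalLossEstimate(
        i_nawm=i_nawm,
        i_csf_min=i_csf,
        f_per_lesion=f_per_lesion,
        f_patient=f_patient,
        n_fiber_voxels=n_vox,
        weights=weights,
        excluded=excluded,
    )


@dataclass
class SubsetComparison:
    """T1-signal reduction of two voxel subsets relative to a reference.

    ``relative_difference_pct`` = (reduction_b − reduction_a)/reduction_a
    × 100: how much more prominent the T1 reduction is in subset b than in
    subset a.  Normalised reductions divide by the reference intensity.
    """

    reduction_a: float
    reduction_b: float
    relative_difference_pct: float
    reduction_a_normalized: float
    reduction_b_normalized: float


def compare_voxel_subsets(
    t1: ScalarVolume,
    subset_a: np.ndarray,
    subset_b: np.ndarray,
    reference: float,
) -> SubsetComparison:
    """Compare mean T1-signal reduction (reference − intensity) between two
    voxel subsets, e.g. fiber-intersected lesional voxels vs the rest of
    the lesion."""
    t1_data = np.asarray(t1.data, dtype=float)
    a = np.asarray(subset_a, dtype=bool)
    b = np.asarray(subset_b, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("both subsets must be non-empty")
    red_a = reference - float(t1_data[a].mean())
    red_b = reference - float(t1_data[b].mean())
    if red_a == 0:
        raise ValueError("subset a has zero reduction; relative difference undefined")
    return SubsetComparison(
        reduction_a=red_a,
        reduction_b=red_b,
        relative_difference_pct=(red_b - red_a) / red_a * 100.0,
        reduction_a_normalized=red_a / reference,
        reduction_b_normalized=red_b / reference,
    )
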