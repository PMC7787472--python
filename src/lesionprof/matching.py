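"""Lesional-streamline selection, truncation/zoning, and non-lesional matching.

A *lesional fiber* is a streamline intersecting exactly one lesion (fibers
through several lesions are excluded to avoid Wallerian-degeneration
confounds, as are fibers touching CSF — dilated by one voxel — or grey
matter).  Each lesional fiber is truncated to the lesion plus 5 mm flanks
on each side, bounded by two limiting planes perpendicular to the fiber.
Matched non-lesional fibers come from the same tract, are clipped by the
same planes, resampled to the same number of points, and accepted when at
least 90% of their samples lie inside a 5 mm diameter tube around the
lesional fiber.  A lesional fiber with fewer than 5 accepted matches is
discarded.

Correspondence between lesional and matched samples is positional: after
equal-count resampling between the same planes, sample *i* of a match
corresponds to sample *i* of the lesional fiber.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (
    arc_lengths,
    point_to_polyline_distance,
    polyline_tangents,
    resample_polyline,
)
from .lesions import LesionMaskSet, _structure
from scipy import ndimage

__all__ = [
    "LimitingPlanes",
    "ZonedFiber",
    "FiberPair",
    "Discard",
    "LesionalSelection",
    "find_lesional_fibers",
    "truncate_and_zone",
    "match_nonlesional",
    "build_fiber_pairs",
]

CORE = "core"
RIM_MINUS = "rim-"
RIM_PLUS = "rim+"


@dataclass(frozen=True)
class LimitingPlanes:
    """Two planes perpendicular to the lesional fiber at the flank ends."""

    point_start: np.ndarray
    normal_start: np.ndarray  # unit, oriented along increasing arc
    point_end: np.ndarray
    normal_end: np.ndarray


@dataclass
class ZonedFiber:
    """A truncated, arc-length-resampled lesional streamline.

    ``zones`` labels every sample: ``core``, ``rim-``/``rim+`` (the rim on
    the proximal/distal side), or a signed flank distance in mm
    (``-5`` … ``-1``, ``+1`` … ``+5``).
    """

    points: np.ndarray
    zones: np.ndarray
    planes: LimitingPlanes
    step: float
    tract_name: str = ""
    lesion_id: int = 0
    fiber_index: int = -1

    @property
    def n_samples(self) -> int:
        return self.points.shape[0]

    def zone_indices(self, zone: str) -> np.ndarray:
        return np.flatnonzero(self.zones == zone)


@dataclass
class FiberPair:
    """One lesional fiber plus its matched non-lesional fibers.

    Every match has the same sample count as the lesional fiber; matching
    is positional (index i ↔ index i).
    """

    lesional: ZonedFiber
    matches: list[np.ndarray]
    match_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.lesional.n_samples
        for m in self.matches:
            if m.shape != (n, 3):
                raise ValueError("matched fiber sample count differs from lesional")

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    @property
    def tract_name(self) -> str:
        return self.lesional.tract_name

    @property
    def lesion_id(self) -> int:
        return self.lesional.lesion_id


@dataclass(frozen=True)
class Discard:
    fiber_index: int
    tract_name: str
    reason: str


@dataclass
class LesionalSelection:
    """Outcome of lesional-fiber selection over one tract."""

    lesional: list[tuple[int, int]]  # (streamline index, lesion id)
    nonlesional_indices: list[int]
    excluded: list[Discard]


def _mask_at(mask: np.ndarray, affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel boolean lookup; points outside the grid are False."""
    inv = np.linalg.inv(affine)
    vox = np.rint(points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    shape = np.asarray(mask.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    out = np.zeros(points.shape[0], dtype=bool)
    if inside.any():
        v = vox[inside]
        out[inside] = np.asarray(mask, dtype=bool)[v[:, 0], v[:, 1], v[:, 2]]
    return out


def _labels_at(labels: np.ndarray, affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    vox = np.rint(points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    shape = np.asarray(labels.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    out = np.zeros(points.shape[0], dtype=labels.dtype)
    if inside.any():
        v = vox[inside]
        out[inside] = labels[v[:, 0], v[:, 1], v[:, 2]]
    return out


def find_lesional_fibers(
    tract,
    lesion_set: LesionMaskSet,
    csf_mask: np.ndarray | None = None,
    gm_mask: np.ndarray | None = None,
    sampling_step: float = 0.5,
) -> LesionalSelection:
    """Partition a tract into lesional fibers, non-lesional candidates and
    exclusions.

    A fiber is lesional when it intersects exactly one lesion; fibers
    through more than one lesion, through the CSF mask dilated by one
    voxel, or through grey matter are excluded.  Fibers touching no lesion
    form the non-lesional candidate pool.
    """
    affine = lesion_set.affine
    csf_dil = None
    if csf_mask is not None and np.asarray(csf_mask).any():
        csf_dil = ndimage.binary_dilation(
            np.asarray(csf_mask, dtype=bool), structure=_structure(lesion_set.connectivity)
        )
    lesional: list[tuple[int, int]] = []
    nonlesional: list[int] = []
    excluded: list[Discard] = []
    for idx, sl in enumerate(tract.streamlines):
        pts = resample_polyline(sl, step=sampling_step)
        hit = np.unique(_labels_at(lesion_set.labels, affine, pts))
        hit = hit[hit > 0]
        if csf_dil is not None and _mask_at(csf_dil, affine, pts).any():
            if hit.size:
                excluded.append(Discard(idx, tract.name, "intersects dilated CSF"))
            continue
        if gm_mask is not None and _mask_at(gm_mask, affine, pts).any():
            if hit.size:
                excluded.append(Discard(idx, tract.name, "intersects grey matter"))
            continue
        if hit.size == 0:
            nonlesional.append(idx)
        elif hit.size == 1:
            lesional.append((idx, int(hit[0])))
        else:
            excluded.append(Discard(idx, tract.name, "intersects multiple lesions"))
    return LesionalSelection(
        lesional=lesional, nonlesional_indices=nonlesional, excluded=excluded
    )


def truncate_and_zone(
    fiber: np.ndarray,
    core_mask: np.ndarray,
    rim_mask: np.ndarray,
    affine: np.ndarray,
    step: float = 1.0,
    flank_mm: float = 5.0,
    tract_name: str = "",
    lesion_id: int = 0,
    fiber_index: int = -1,
) -> ZonedFiber | Discard:
    """Arc-length resample a lesional fiber, truncate it to the lesion plus
    flanks, and label every sample with its zone.

    The fiber is resampled at ``step`` mm along its arc.  The lesion run is
    the span from the first to the last in-lesion sample; samples inside
    the eroded core are ``core``, remaining in-lesion samples are rim
    (side-specific).  Flanks extend exactly ``flank_mm/step`` samples
    beyond the lesion run on each side, so flank distance is measured
    along the arc, not as a chord.  Limiting planes sit at the two flank
    endpoints with normals along the local tangent.

    Fibers with no core contact or without room for full flanks are
    discarded (the reason is returned, never raised).
    """

    def _discard(reason: str) -> Discard:
        return Discard(fiber_index, tract_name, reason)

    flank_n = int(round(flank_mm / step))
    pts = resample_polyline(fiber, step=step)
    in_core = _mask_at(core_mask, affine, pts)
    in_rim = _mask_at(rim_mask, affine, pts)
    in_lesion = in_core | in_rim
    if not in_lesion.any():
        return _discard("no lesion contact")
    run = np.flatnonzero(in_lesion)
    lo, hi = int(run[0]), int(run[-1])

    zones = np.empty(pts.shape[0], dtype=object)
    core_idx = np.flatnonzero(in_core)
    if core_idx.size == 0:
        return _discard("no core contact")
    c0, c1 = int(core_idx[0]), int(core_idx[-1])
    zones[c0 : c1 + 1] = CORE
    zones[lo:c0] = RIM_MINUS
    zones[c1 + 1 : hi + 1] = RIM_PLUS
    # the 13-point profile needs one rim value per side; when sampling
    # skipped the thin rim shell, the outermost in-lesion sample stands in
    if c0 == lo:
        zones[lo] = RIM_MINUS
    if c1 == hi:
        zones[hi] = RIM_PLUS
    if not np.any(zones[lo : hi + 1] == CORE):
        return _discard("no core contact")

    start, end = lo - flank_n, hi + flank_n
    if start < 0 or end >= pts.shape[0]:
        return _discard("insufficient flank")
    for k in range(1, flank_n + 1):
        zones[lo - k] = f"-{k}"
        zones[hi + k] = f"+{k}"

    sel = slice(start, end + 1)
    tangents = polyline_tangents(pts)
    planes = LimitingPlanes(
        point_start=pts[start].copy(),
        normal_start=tangents[start].copy(),
        point_end=pts[end].copy(),
        normal_end=tangents[end].copy(),
    )
    return ZonedFiber(
        points=pts[sel].copy(),
        zones=zones[sel].copy(),
        planes=planes,
        step=step,
        tract_name=tract_name,
        lesion_id=lesion_id,
        fiber_index=fiber_index,
    )


def _plane_crossings(points: np.ndarray, plane_point, plane_normal) -> np.ndarray:
    """Arc positions where a polyline crosses a plane (sign changes of the
    signed distance, linearly interpolated)."""
    s = (points - plane_point) @ plane_normal
    arc = arc_lengths(points)
    sign_change = np.flatnonzero(s[:-1] * s[1:] < 0)
    crossings = [
        arc[i] + (arc[i + 1] - arc[i]) * s[i] / (s[i] - s[i + 1]) for i in sign_change
    ]
    crossings.extend(arc[np.flatnonzero(s == 0)])
    return np.sort(np.asarray(crossings, dtype=float))


def _extract_arc(points: np.ndarray, t0: float, t1: float, n: int) -> np.ndarray:
    arc = arc_lengths(points)
    t = np.linspace(t0, t1, n)
    return np.stack([np.interp(t, arc, points[:, k]) for k in range(3)], axis=1)


def match_nonlesional(
    zoned: ZonedFiber,
    candidates: list[np.ndarray],
    candidate_indices: list[int] | None = None,
    tube_diameter: float = 5.0,
    tube_fraction: float = 0.90,
    min_matches: int = 5,
) -> FiberPair | Discard:
    """Match non-lesional fibers to a zoned lesional fiber.

    Each candidate is oriented along the lesional fiber, clipped between
    the two limiting planes, resampled to the lesional sample count, and
    accepted when it crosses both planes and at least ``tube_fraction`` of
    its samples lie within ``tube_diameter/2`` of the lesional polyline.
    Acceptance is per-candidate (no competition), so the result does not
    depend on candidate order.
    """
    if candidate_indices is None:
        candidate_indices = list(range(len(candidates)))
    n = zoned.n_samples
    radius = tube_diameter / 2.0
    lesional_dir = zoned.points[-1] - zoned.points[0]
    # bounding-box prefilter around the lesional fiber
    lo = zoned.points.min(axis=0) - radius
    hi = zoned.points.max(axis=0) + radius

    accepted: list[np.ndarray] = []
    accepted_idx: list[int] = []
    planes = zoned.planes
    for cand, cidx in zip(candidates, candidate_indices):
        cand = np.asarray(cand, dtype=float)
        if np.any(cand.max(axis=0) < lo) or np.any(cand.min(axis=0) > hi):
            continue
        if (cand[-1] - cand[0]) @ lesional_dir < 0:
            cand = cand[::-1]
        t_a = _plane_crossings(cand, planes.point_start, planes.normal_start)
        t_b = _plane_crossings(cand, planes.point_end, planes.normal_end)
        if t_a.size == 0 or t_b.size == 0:
            continue
        t0, t1 = float(t_a[0]), float(t_b[-1])
        if t1 - t0 < zoned.step:
            continue
        clipped = _extract_arc(cand, t0, t1, n)
        dists = point_to_polyline_distance(clipped, zoned.points)
        if np.mean(dists <= radius) >= tube_fraction:
            accepted.append(clipped)
            accepted_idx.append(cidx)
    if len(accepted) < min_matches:
        return Discard(
            zoned.fiber_index,
            zoned.tract_name,
            f"insufficient matches ({len(accepted)} < {min_matches})",
        )
    return FiberPair(lesional=zoned, matches=accepted, match_indices=accepted_idx)


def build_fiber_pairs(
    tract,
    lesion_set: LesionMaskSet,
    csf_mask: np.ndarray | None = None,
    gm_mask: np.ndarray | None = None,
    step: float = 1.0,
    flank_mm: float = 5.0,
    tube_diameter: float = 5.0,
    tube_fraction: float = 0.90,
    min_matches: int = 5,
) -> tuple[list[FiberPair], list[Discard]]:
    """Run selection → truncation/zoning → matching over one tract."""
    selection = find_lesional_fibers(tract, lesion_set, csf_mask, gm_mask)
    discards = list(selection.excluded)
    candidates = [
        resample_polyline(tract.streamlines[i], step=step)
        for i in selection.nonlesional_indices
    ]
    pairs: list[FiberPair] = []
    for idx, lesion_id in selection.lesional:
        zoned = truncate_and_zone(
            tract.streamlines[idx],
            lesion_set.core_mask(lesion_id),
            lesion_set.rim_mask(lesion_id),
            lesion_set.affine,
            step=step,
            flank_mm=flank_mm,
            tract_name=tract.name,
            lesion_id=lesion_id,
            fiber_index=idx,
        )
        if isinstance(zoned, Discard):
            discards.append(zoned)
            continue
        result = match_nonlesional(
            zoned,
            candidates,
            candidate_indices=selection.nonlesional_indices,
            tube_diameter=tube_diameter,
            tube_fraction=tube_fraction,
            min_matches=min_matches,
        )
        if isinstance(result, Discard):
            discards.append(result)
        else:
            pairs.append(result)
    return pairs, discards


def discard_table(discards: list[Discard]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"fiber_index": d.fiber_index, "tract": d.tract_name, "reason": d.reason}
            for d in discards
        ],
        columns=["fiber_index", "tract", "reason"],
    )
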