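"""NIfTI scalar-volume and TRK/TCK streamline I/O plus voxel/world geometry.

Conventions used throughout the package:

* all streamline/point geometry is world (RAS) millimetres;
* voxel indices are 0-based with the voxel-centre convention (the affine
  maps integer voxel indices to the world coordinate of the voxel centre);
* scalar diffusivity maps are in μm²/ms.

Default map sampling is nearest-neighbour: profile statements are about
the voxels a streamline traverses, not interpolated values. Trilinear
sampling is available for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import streamlines as nib_streamlines
from scipy import ndimage

__all__ = [
    "ScalarVolume",
    "DiffusivityMaps",
    "Tract",
    "load_volume",
    "save_volume",
    "maps_from_tensor",
    "load_tract",
    "save_tract",
    "sample_volume",
]


@dataclass
class ScalarVolume:
    """A 3-D scalar grid with a voxel-to-world (mm) affine."""

    data: np.ndarray
    affine: np.ndarray
    units: str = "um^2/ms"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (N, 3) to continuous voxel coordinates."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def sample(self, points: np.ndarray, mode: str = "nearest") -> np.ndarray:
        return sample_volume(self, points, mode=mode)


def load_volume(path: str | Path, units: str = "um^2/ms") -> ScalarVolume:
    """Load a 3-D NIfTI volume."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return ScalarVolume(data=data, affine=np.asarray(img.affine), units=units)


def save_volume(vol: ScalarVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    nib.save(img, str(path))


@dataclass
class DiffusivityMaps:
    """Co-registered axial, radial and mean diffusivity maps (μm²/ms)."""

    ad: ScalarVolume
    rd: ScalarVolume
    md: ScalarVolume

    def __post_init__(self) -> None:
        for name, vol in (("rd", self.rd), ("md", self.md)):
            if vol.shape != self.ad.shape:
                raise ValueError(f"{name} grid shape differs from ad")
            if not np.allclose(vol.affine, self.ad.affine, atol=1e-9):
                raise ValueError(f"{name} affine differs from ad")

    @classmethod
    def from_ad_rd(cls, ad: ScalarVolume, rd: ScalarVolume) -> "DiffusivityMaps":
        """Build maps with MD recomputed from the identity MD = (AD + 2·RD)/3."""
        md = ScalarVolume(
            data=(np.asarray(ad.data, float) + 2.0 * np.asarray(rd.data, float)) / 3.0,
            affine=ad.affine,
            units=ad.units,
        )
        return cls(ad=ad, rd=rd, md=md)

    @property
    def affine(self) -> np.ndarray:
        return self.ad.affine

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ad.shape


def maps_from_tensor(
    tensor: np.ndarray, affine: np.ndarray, order: str = "lower"
) -> DiffusivityMaps:
    """Derive AD/RD/MD maps from a 6-component symmetric tensor volume.

    The 6 components follow the NIfTI lower-triangular convention
    (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz).  Per voxel the eigenvalues
    λ1 ≥ λ2 ≥ λ3 give AD = λ1, RD = (λ2 + λ3)/2, MD = (λ1 + λ2 + λ3)/3.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 4 or tensor.shape[-1] != 6:
        raise ValueError("tensor volume must have shape (X, Y, Z, 6)")
    if not np.all(np.isfinite(tensor)):
        raise ValueError("tensor volume contains non-finite entries")
    if order != "lower":
        raise ValueError("only the lower-triangular component order is supported")
    xx, xy, yy, xz, yz, zz = np.moveaxis(tensor, -1, 0)
    mats = np.empty(tensor.shape[:3] + (3, 3), dtype=float)
    mats[..., 0, 0] = xx
    mats[..., 1, 1] = yy
    mats[..., 2, 2] = zz
    mats[..., 0, 1] = mats[..., 1, 0] = xy
    mats[..., 0, 2] = mats[..., 2, 0] = xz
    mats[..., 1, 2] = mats[..., 2, 1] = yz
    evals = np.linalg.eigvalsh(mats)  # ascending
    ad = ScalarVolume(evals[..., 2], affine)
    rd = ScalarVolume((evals[..., 0] + evals[..., 1]) / 2.0, affine)
    md = ScalarVolume(evals.mean(axis=-1), affine)
    return DiffusivityMaps(ad=ad, rd=rd, md=md)


@dataclass
class Tract:
    """A named bundle of streamlines in world-mm coordinates."""

    name: str
    streamlines: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for i, sl in enumerate(self.streamlines):
            sl = np.asarray(sl, dtype=float)
            if sl.ndim != 2 or sl.shape[1] != 3 or sl.shape[0] < 2:
                raise ValueError(f"streamline {i} must be an (N>=2, 3) polyline")
            if not np.all(np.isfinite(sl)):
                raise ValueError(f"streamline {i} has non-finite coordinates")
            cleaned.append(sl)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)


def load_tract(path: str | Path, name: str | None = None) -> Tract:
    """Load a TRK or TCK file as world/RAS-mm streamlines.

    nibabel applies the on-disk convention (TRK voxel-corner offsets, TCK
    native mm) so both formats load to the same world coordinates.
    """
    path = Path(path)
    tfile = nib_streamlines.load(str(path))  # to_world applied by default
    sls = [np.asarray(s, dtype=float) for s in tfile.streamlines]
    if not sls:
        warnings.warn(f"{path}: tract file contains no streamlines", stacklevel=2)
    return Tract(name=name or path.stem, streamlines=sls)


def save_tract(
    tract: Tract,
    path: str | Path,
    reference: ScalarVolume | None = None,
) -> None:
    """Save a tract to TRK or TCK (chosen by extension).

    TRK stores voxel-order metadata; pass a ``reference`` volume so the
    header carries its grid, otherwise an identity 1-mm header is written.
    """
    path = Path(path)
    tractogram = nib_streamlines.Tractogram(
        [np.asarray(s, dtype=float) for s in tract.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith(".tck"):
        nib_streamlines.save(tractogram, str(path))
        return
    if not suffix.endswith(".trk"):
        raise ValueError(f"unknown streamline format: {path}")
    header = {}
    if reference is not None:
        header[nib_streamlines.trk.Field.VOXEL_TO_RASMM] = reference.affine.astype(
            np.float32
        )
        header[nib_streamlines.trk.Field.VOXEL_SIZES] = tuple(
            np.sqrt((reference.affine[:3, :3] ** 2).sum(axis=0)).astype(np.float32)
        )
        header[nib_streamlines.trk.Field.DIMENSIONS] = tuple(
            np.asarray(reference.shape, dtype=np.int16)
        )
    nib_streamlines.save(tractogram, str(path), header=header or None)


def sample_volume(
    vol: ScalarVolume, points: np.ndarray, mode: str = "nearest"
) -> np.ndarray:
    """Sample a volume at world-mm points.

    Returns one value per point; points outside the grid are NaN.  Modes:
    ``nearest`` (default, voxel value at the containing voxel) and
    ``trilinear``.
    """
    if mode not in ("nearest", "trilinear"):
        raise ValueError(f"unknown sampling mode: {mode!r}")
    vox = vol.world_to_voxel(points)
    shape = np.asarray(vol.shape, dtype=float)
    # a point belongs to the grid if its containing voxel (rounded index)
    # exists; consistent with the voxel-centre convention
    inside = np.all((vox > -0.5) & (vox < shape - 0.5), axis=1)
    out = np.full(vox.shape[0], np.nan)
    if not np.any(inside):
        return out
    data = np.asarray(vol.data, dtype=float)
    if mode == "nearest":
        idx = np.rint(vox[inside]).astype(int)
        idx = np.clip(idx, 0, np.asarray(vol.shape) - 1)
        out[inside] = data[idx[:, 0], idx[:, 1], idx[:, 2]]
    else:
        out[inside] = ndimage.map_coordinates(
            data, vox[inside].T, order=1, mode="nearest"
        )
    return out
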