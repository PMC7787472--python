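"""Synthetic diffusivity/T1 phantoms with known axonal-loss ground truth.

The phantom emulates piecewise-homogeneous white matter (AD 1.22, RD 0.59
μm²/ms) traversed by analytic fiber bundles, plus ellipsoidal lesions whose
diffusivities follow the two-compartment forward model at a known
axonal-loss fraction ``f`` and demyelination fraction ``m``.  T1 intensity
is linear in ``f`` between the NAWM and CSF anchors.  A CSF slab and a
grey-matter slab border the volume so the CSF/GM exclusion rules are
exercisable, and small NAWM / CSF reference ROIs are placed for the
T1 anchors.

Streamlines are generated analytically along each bundle centerline with
per-streamline lateral offsets drawn uniformly over the bundle
cross-section (no tractography).  Everything is deterministic for a fixed
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import model
from .geometry import point_to_polyline_distance, resample_polyline
from .lesions import LesionMaskSet
from .volumes import DiffusivityMaps, ScalarVolume, Tract, save_tract, save_volume

__all__ = [
    "BundleSpec",
    "LesionSpec",
    "PhantomSpec",
    "TissueMasks",
    "PhantomData",
    "generate_phantom",
    "add_crossing_contamination",
    "example_spec",
    "write_phantom",
]


@dataclass
class BundleSpec:
    """A fiber bundle: tube of given radius around a centerline polyline.

    2000 streamlines per tract matches standard per-tract tractogram
    density; normal-tissue diffusivities default to coherent white matter.
    """

    centerline: np.ndarray  # (M, 3) world mm
    radius: float = 6.0
    n_streamlines: int = 2000
    ad_normal: float = 1.22
    rd_normal: float = 0.59
    name: str = "bundle"

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be an (M, 3) polyline")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")


@dataclass
class LesionSpec:
    """Ellipsoidal lesion with ground-truth pathology (f, m)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    f_axonal_loss: float = 0.4
    m_demyelination: float = 1.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be positive")
        if not 0.0 <= self.f_axonal_loss <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if not 0.0 <= self.m_demyelination <= 1.0:
            raise ValueError("m must lie in [0, 1]")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (48, 28, 28)
    voxel_size: float = 1.0
    bundles: list[BundleSpec] = field(default_factory=list)
    lesions: list[LesionSpec] = field(default_factory=list)
    noise_sd: float = 0.0  # μm²/ms, i.i.d. Gaussian on AD and RD
    t1_noise_sd: float = 0.0  # a.u.
    seed: int = 0
    t1_nawm: float = 3326.0  # cohort-average NAWM T1 anchor (a.u.)
    t1_csf: float = 863.0  # cohort-average minimum CSF T1 anchor (a.u.)
    csf_slab_vox: int = 3  # CSF slab thickness at the low-y face
    gm_slab_vox: int = 3  # grey-matter slab at the high-y face

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.noise_sd < 0 or self.t1_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass
class TissueMasks:
    csf: np.ndarray
    gm: np.ndarray
    nawm_rois: np.ndarray
    csf_rois: np.ndarray
    wm: np.ndarray
    affine: np.ndarray


@dataclass
class PhantomData:
    maps: DiffusivityMaps
    t1: ScalarVolume
    lesions: LesionMaskSet
    tissues: TissueMasks
    tracts: list[Tract]
    ground_truth: dict
    spec: PhantomSpec


def example_spec(
    seed: int = 0,
    n_streamlines: int = 2000,
    f: float = 0.4,
    m: float = 1.0,
    noise_sd: float = 0.0,
) -> PhantomSpec:
    """Canonical single-bundle, single-lesion phantom.

    A straight left–right bundle (radius 6 mm) crosses an ellipsoidal
    lesion (semi-axes 6 × 2.5 × 2.5 mm) centred on its axis, flanked by a
    CSF slab and a grey-matter slab at the volume faces.
    """
    centerline = np.array([[2.0, 14.0, 14.0], [45.0, 14.0, 14.0]])
    return PhantomSpec(
        bundles=[
            BundleSpec(centerline=centerline, radius=6.0, n_streamlines=n_streamlines)
        ],
        lesions=[
            LesionSpec(
                center=(24.0, 14.0, 14.0),
                semi_axes=(6.0, 2.5, 2.5),
                f_axonal_loss=f,
                m_demyelination=m,
            )
        ],
        noise_sd=noise_sd,
        seed=seed,
    )


def spec_from_dict(raw: dict) -> PhantomSpec:
    """Build a PhantomSpec from a plain (YAML-loaded) dictionary."""
    raw = dict(raw)
    bundles = [BundleSpec(**b) for b in raw.pop("bundles", [])]
    lesions = [LesionSpec(**{
        **l,
        "center": tuple(l["center"]),
        "semi_axes": tuple(l["semi_axes"]),
    }) for l in raw.pop("lesions", [])]
    if "grid_shape" in raw:
        raw["grid_shape"] = tuple(raw["grid_shape"])
    return PhantomSpec(bundles=bundles, lesions=lesions, **raw)


def _voxel_centers(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def _perp_frame(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean_t = tangents.mean(axis=0)
    ref = np.eye(3)[np.argmin(np.abs(mean_t))]
    n1 = np.cross(tangents, ref)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangents, n1)
    n2 /= np.linalg.norm(n2, axis=1, keepdims=True)
    return n1, n2


def _bundle_streamlines(
    bundle: BundleSpec, rng: np.random.Generator, step: float = 0.5
) -> list[np.ndarray]:
    center = resample_polyline(bundle.centerline, step=step)
    grad = np.gradient(center, axis=0)
    tangents = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    n1, n2 = _perp_frame(tangents)
    radii = bundle.radius * np.sqrt(rng.uniform(size=bundle.n_streamlines))
    thetas = rng.uniform(0.0, 2.0 * np.pi, size=bundle.n_streamlines)
    out = []
    for r, th in zip(radii, thetas):
        offset = r * (np.cos(th) * n1 + np.sin(th) * n2)
        out.append(center + offset)
    return out


def generate_phantom(
    spec: PhantomSpec, params: model.ModelParams | None = None
) -> PhantomData:
    """Generate co-registered AD/RD/MD + T1 volumes, masks and streamlines.

    Lesion voxels get AD = AD_normal + ΔAD(f) and RD = RD_normal + ΔRD(f, m)
    from the forward model; T1 = I_NAWM − f·(I_NAWM − I_CSF).  MD is always
    recomputed as (AD + 2·RD)/3, also after noise is added.
    """
    params = params or model.ModelParams()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    centers = _voxel_centers(shape, affine)

    jj = np.indices(shape)[1]
    csf = jj < spec.csf_slab_vox
    gm = jj >= shape[1] - spec.gm_slab_vox

    # bundle occupancy (used only for sanity warnings and NAWM ROI checks)
    wm_extent = np.array([s * spec.voxel_size for s in shape])
    bundle_dist = np.full(centers.shape[0], np.inf)
    for bundle in spec.bundles:
        d = point_to_polyline_distance(centers, bundle.centerline)
        bundle_dist = np.minimum(bundle_dist, d)
    in_bundle = (
        (bundle_dist.reshape(shape) <= max((b.radius for b in spec.bundles), default=0))
        if spec.bundles
        else np.zeros(shape, dtype=bool)
    )

    # lesion labels (later lesions overwrite earlier ones where they overlap)
    labels = np.zeros(shape, dtype=np.int32)
    for i, lesion in enumerate(spec.lesions, start=1):
        rel = (centers - np.asarray(lesion.center)) / np.asarray(lesion.semi_axes)
        inside = (rel**2).sum(axis=1).reshape(shape) <= 1.0
        inside &= ~csf & ~gm
        if not (inside & in_bundle).any():
            warnings.warn(
                f"lesion {i} does not overlap any bundle; no lesional fibers "
                "will exist",
                stacklevel=2,
            )
        labels[inside] = i

    ad_n = spec.bundles[0].ad_normal if spec.bundles else params.ad_normal
    rd_n = spec.bundles[0].rd_normal if spec.bundles else params.rd_normal
    ad = np.full(shape, ad_n, dtype=float)
    rd = np.full(shape, rd_n, dtype=float)
    t1 = np.full(shape, spec.t1_nawm, dtype=float)
    ad[csf] = rd[csf] = 3.0  # free water
    ad[gm] = rd[gm] = 0.8  # near-isotropic grey matter
    t1[csf] = spec.t1_csf
    t1[gm] = 0.75 * spec.t1_nawm
    for i, lesion in enumerate(spec.lesions, start=1):
        vox = labels == i
        state = model.LesionState(f=lesion.f_axonal_loss, m=lesion.m_demyelination)
        ad[vox] = ad_n + model.delta_ad(state, params)
        rd[vox] = rd_n + model.delta_rd(state, params)
        t1[vox] = spec.t1_nawm - lesion.f_axonal_loss * (spec.t1_nawm - spec.t1_csf)

    if spec.noise_sd > 0:
        ad = ad + rng.normal(0.0, spec.noise_sd, size=shape)
        rd = rd + rng.normal(0.0, spec.noise_sd, size=shape)
    if spec.t1_noise_sd > 0:
        t1 = t1 + rng.normal(0.0, spec.t1_noise_sd, size=shape)

    maps = DiffusivityMaps.from_ad_rd(
        ScalarVolume(ad, affine), ScalarVolume(rd, affine)
    )
    t1_vol = ScalarVolume(t1, affine, units="a.u.")

    # reference ROIs: NAWM spheres on the first bundle, CSF box in the slab
    nawm = np.zeros(shape, dtype=bool)
    if spec.bundles:
        cl = spec.bundles[0].centerline
        lesion_centers = [np.asarray(l.center) for l in spec.lesions]
        for frac in (0.15, 0.85):
            p = cl[0] + frac * (cl[-1] - cl[0])
            ok = all(
                np.linalg.norm(p - c) > max(l.semi_axes) + 3.0
                for c, l in zip(lesion_centers, spec.lesions)
            )
            if ok:
                sphere = (
                    np.linalg.norm(centers - p, axis=1).reshape(shape) <= 2.5
                )
                nawm |= sphere & (labels == 0) & ~csf & ~gm
    csf_roi = np.zeros(shape, dtype=bool)
    csf_roi[
        shape[0] // 4 : shape[0] // 4 + 4, : max(1, spec.csf_slab_vox - 1),
        shape[2] // 2 - 2 : shape[2] // 2 + 2,
    ] = True
    csf_roi &= csf

    tissues = TissueMasks(
        csf=csf, gm=gm, nawm_rois=nawm, csf_rois=csf_roi,
        wm=~csf & ~gm, affine=affine,
    )
    lesion_set = LesionMaskSet(labels=labels, affine=affine)

    tracts = []
    lo_world = -0.5 * spec.voxel_size
    hi_world = wm_extent - 0.5 * spec.voxel_size
    for b, bundle in enumerate(spec.bundles):
        name = bundle.name if bundle.name != "bundle" else f"bundle{b}"
        sls = _bundle_streamlines(bundle, rng)
        pts = np.concatenate(sls)
        if np.any(pts < lo_world) or np.any(pts > hi_world):
            raise ValueError(f"bundle {name!r} extends outside the grid")
        tracts.append(Tract(name=name, streamlines=sls))

    ground_truth = {
        "seed": spec.seed,
        "t1_nawm": spec.t1_nawm,
        "t1_csf": spec.t1_csf,
        "noise_sd": spec.noise_sd,
        "lesions": [
            {
                "id": i + 1,
                "center": list(map(float, l.center)),
                "semi_axes": list(map(float, l.semi_axes)),
                "f_axonal_loss": l.f_axonal_loss,
                "m_demyelination": l.m_demyelination,
            }
            for i, l in enumerate(spec.lesions)
        ],
    }
    return PhantomData(
        maps=maps, t1=t1_vol, lesions=lesion_set, tissues=tissues,
        tracts=tracts, ground_truth=ground_truth, spec=spec,
    )


def add_crossing_contamination(
    maps: DiffusivityMaps, region: np.ndarray, delta_rd: float | np.ndarray
) -> DiffusivityMaps:
    """Perturb (AD, RD) along the MD-preserving direction in a region.

    Crossing fibers lower diffusivity along the main axis and raise it
    perpendicular to it, so δRD = +delta_rd and δAD = −2·delta_rd, leaving
    MD = (AD + 2·RD)/3 untouched.  ``delta_rd`` may be a scalar or an array
    with one value per region voxel.  Raises if the perturbation would make
    RD exceed AD anywhere (nonphysical eigenvalue ordering).
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != maps.shape:
        raise ValueError("region mask shape differs from the maps")
    ad = np.asarray(maps.ad.data, dtype=float).copy()
    rd = np.asarray(maps.rd.data, dtype=float).copy()
    delta = np.asarray(delta_rd, dtype=float)
    if delta.ndim > 0 and delta.shape != (int(region.sum()),):
        raise ValueError("per-voxel delta_rd must have one value per region voxel")
    ad[region] = ad[region] - 2.0 * delta
    rd[region] = rd[region] + delta
    if np.any(rd[region] > ad[region]):
        raise ValueError("contamination would make RD exceed AD (nonphysical)")
    return DiffusivityMaps.from_ad_rd(
        ScalarVolume(ad, maps.affine, units=maps.ad.units),
        ScalarVolume(rd, maps.affine, units=maps.rd.units),
    )


def write_phantom(data: PhantomData, out_dir) -> None:
    """Write the phantom to disk: NIfTI volumes/masks, one TRK per tract
    and a YAML ground-truth sidecar."""
    from pathlib import Path

    import yaml

    out = Path(out_dir)
    (out / "tracts").mkdir(parents=True, exist_ok=True)
    affine = data.maps.affine
    save_volume(data.maps.ad, out / "ad.nii.gz")
    save_volume(data.maps.rd, out / "rd.nii.gz")
    save_volume(data.maps.md, out / "md.nii.gz")
    save_volume(data.t1, out / "t1.nii.gz")
    save_volume(
        ScalarVolume(data.lesions.labels.astype(np.int16), affine, units="label"),
        out / "lesion_labels.nii.gz",
    )
    for name, mask in (
        ("csf", data.tissues.csf),
        ("gm", data.tissues.gm),
        ("nawm_rois", data.tissues.nawm_rois),
        ("csf_rois", data.tissues.csf_rois),
    ):
        save_volume(
            ScalarVolume(mask.astype(np.uint8), affine, units="mask"),
            out / f"{name}.nii.gz",
        )
    for tract in data.tracts:
        save_tract(tract, out / "tracts" / f"{tract.name}.trk", reference=data.maps.ad)
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(data.ground_truth, fh, sort_keys=True)
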