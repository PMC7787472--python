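"""End-to-end orchestration: config, validation, and the profiling pipeline.

Every numeric constant of the method (resampling step, flank length, tube
diameter and fraction, minimum matches, lesion size filter, erosion
connectivity, model constants) lives in one :class:`RunConfig` record so a
run is fully auditable; outputs carry a provenance file with the config,
its hash, the seed and the package version.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, model
from .lesions import LesionMaskSet, estimate_axonal_loss, filter_lesions
from .matching import build_fiber_pairs, discard_table
from .profiles import (
    aggregate_lesion,
    aggregate_patient,
    build_pair_profile,
    lesion_table,
    md_normalize,
    pair_table,
    patient_table,
    profile_summary,
)
from .volumes import DiffusivityMaps, ScalarVolume, load_tract, load_volume

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "validate_inputs",
    "EXIT_AFFINE_MISMATCH",
    "EXIT_NO_LESIONS",
    "EXIT_NO_PAIRS",
]

EXIT_AFFINE_MISMATCH = 2
EXIT_NO_LESIONS = 3
EXIT_NO_PAIRS = 4


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int = 1) -> None:
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class RunConfig:
    """All inputs and numeric constants of a profiling run."""

    ad_path: str = ""
    rd_path: str = ""
    md_path: str = ""  # optional; recomputed from AD/RD when empty
    t1_path: str = ""
    lesion_mask_path: str = ""
    csf_mask_path: str = ""
    gm_mask_path: str = ""
    nawm_roi_path: str = ""
    csf_roi_path: str = ""
    tracts_dir: str = ""
    step_mm: float = 1.0
    flank_mm: float = 5.0
    tube_diameter_mm: float = 5.0
    tube_fraction: float = 0.90
    min_matches: int = 5
    min_lesion_mm3: float = 100.0
    erosion_connectivity: int = 6
    md_normalize: bool = True
    model_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("step_mm", "flank_mm", "tube_diameter_mm", "min_lesion_mm3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.tube_fraction <= 1.0:
            raise ValueError("tube_fraction must lie in (0, 1]")
        if self.min_matches < 1:
            raise ValueError("min_matches must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def params(self) -> model.ModelParams:
        return model.ModelParams(**self.model_params)

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()


def _load_mask(path: str) -> np.ndarray | None:
    if not path:
        return None
    return np.asarray(load_volume(path).data) > 0


def _load_inputs(config: RunConfig):
    ad = load_volume(config.ad_path)
    rd = load_volume(config.rd_path)
    if config.md_path:
        md = load_volume(config.md_path)
        maps = DiffusivityMaps(ad=ad, rd=rd, md=md)
    else:
        maps = DiffusivityMaps.from_ad_rd(ad, rd)
    lesion_img = load_volume(config.lesion_mask_path)
    volumes = {"t1": None}
    if config.t1_path:
        volumes["t1"] = load_volume(config.t1_path, units="a.u.")
    for vol in [lesion_img] + ([volumes["t1"]] if volumes["t1"] is not None else []):
        if vol.shape != maps.shape or not np.allclose(
            vol.affine, maps.affine, atol=1e-6
        ):
            raise PipelineError(
                "input volumes are not co-registered (grid/affine mismatch)",
                EXIT_AFFINE_MISMATCH,
            )
    labels = np.asarray(lesion_img.data)
    if np.issubdtype(labels.dtype, np.floating):
        labels = np.rint(labels).astype(np.int32)
    if labels.max() <= 1:
        lesion_set = LesionMaskSet.from_binary(
            labels > 0, maps.affine, connectivity=config.erosion_connectivity
        )
    else:
        lesion_set = LesionMaskSet(
            labels=labels.astype(np.int32),
            affine=maps.affine,
            connectivity=config.erosion_connectivity,
        )
    masks = {
        "csf": _load_mask(config.csf_mask_path),
        "gm": _load_mask(config.gm_mask_path),
        "nawm_roi": _load_mask(config.nawm_roi_path),
        "csf_roi": _load_mask(config.csf_roi_path),
    }
    tracts = []
    if config.tracts_dir:
        for path in sorted(Path(config.tracts_dir).iterdir()):
            if path.suffix.lower() in (".trk", ".tck"):
                tracts.append(load_tract(path))
    return maps, volumes["t1"], lesion_set, masks, tracts


def _fiber_voxel_mask(pairs, lesion_set: LesionMaskSet) -> np.ndarray:
    """Lesional voxels intersected by at least one analysed lesional fiber."""
    mask = np.zeros(lesion_set.labels.shape, dtype=bool)
    inv = np.linalg.inv(lesion_set.affine)
    for pair in pairs:
        pts = pair.lesional.points
        vox = np.rint(pts @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        inside = np.all((vox >= 0) & (vox < np.asarray(mask.shape)), axis=1)
        v = vox[inside]
        mask[v[:, 0], v[:, 1], v[:, 2]] = True
    return mask & lesion_set.any_lesion


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the full single-streamline profiling pipeline and write outputs.

    Writes pair/lesion/patient profile tables, the axonal-loss table, a
    measured-vs-modelled comparison, the discard log and a provenance
    record.  Deterministic for a fixed config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps, t1, lesion_set, masks, tracts = _load_inputs(config)
    params = config.params()

    lesion_set = filter_lesions(lesion_set, config.min_lesion_mm3)
    if not lesion_set.ids:
        raise PipelineError("no lesions pass the size filter", EXIT_NO_LESIONS)

    all_pairs, all_discards = [], []
    for tract in tracts:
        pairs, discards = build_fiber_pairs(
            tract,
            lesion_set,
            csf_mask=masks["csf"],
            gm_mask=masks["gm"],
            step=config.step_mm,
            flank_mm=config.flank_mm,
            tube_diameter=config.tube_diameter_mm,
            tube_fraction=config.tube_fraction,
            min_matches=config.min_matches,
        )
        all_pairs.extend(pairs)
        all_discards.extend(discards)
    if not all_pairs:
        discard_table(all_discards).to_csv(out / "discards.csv", index=False)
        raise PipelineError("no lesional/non-lesional fiber pairs found", EXIT_NO_PAIRS)

    pair_profiles = []
    for pair in all_pairs:
        prof = build_pair_profile(pair, maps)
        if hasattr(prof, "reason"):  # Discard
            all_discards.append(prof)
            continue
        if config.md_normalize:
            prof = md_normalize(prof)
        pair_profiles.append(prof)
    if not pair_profiles:
        raise PipelineError("all fiber pairs were discarded", EXIT_NO_PAIRS)

    by_lesion: dict[int, list] = {}
    for prof in pair_profiles:
        by_lesion.setdefault(prof.lesion_id, []).append(prof)
    lesion_profiles = [
        aggregate_lesion(group) for _, group in sorted(by_lesion.items())
    ]
    patient = aggregate_patient(lesion_profiles)

    pair_table(pair_profiles).to_csv(out / "pair_profiles.csv", index=False)
    lesion_table(lesion_profiles).to_csv(out / "lesion_profiles.csv", index=False)
    patient_table(patient).to_csv(out / "patient_profile.csv", index=False)
    profile_summary([patient]).to_csv(out / "profile_summary.csv", index=False)
    discard_table(all_discards).to_csv(out / "discards.csv", index=False)

    # T1-derived axonal loss over fiber-intersected lesional voxels
    axloss = None
    if t1 is not None and masks["nawm_roi"] is not None and masks["csf_roi"] is not None:
        fiber_mask = _fiber_voxel_mask(all_pairs, lesion_set)
        fiber_counts = {k: len(v) for k, v in by_lesion.items()}
        axloss = estimate_axonal_loss(
            t1, lesion_set, fiber_mask, masks["nawm_roi"], masks["csf_roi"],
            fiber_counts=fiber_counts,
        )
        axloss.table().to_csv(out / "axonal_loss.csv", index=False)

        rows = []
        for lp in lesion_profiles:
            if lp.lesion_id not in axloss.f_per_lesion:
                continue
            f_hat = axloss.f_per_lesion[lp.lesion_id]
            state = model.LesionState(f=f_hat, m=1.0)
            inv = model.invert(lp.delta_ad[6], lp.delta_rd[6], params)
            rows.append(
                {
                    "lesion_id": lp.lesion_id,
                    "f_t1": f_hat,
                    "measured_delta_ad_core": lp.delta_ad[6],
                    "measured_delta_rd_core": lp.delta_rd[6],
                    "model_delta_ad": model.delta_ad(state, params),
                    "model_delta_rd": model.delta_rd(state, params),
                    "f_from_delta_ad": inv.f,
                    "m_from_delta_rd": inv.m,
                    "m_reliable": inv.m_reliable,
                }
            )
        comparison = pd.DataFrame(rows)
        comparison.to_csv(out / "model_comparison.csv", index=False)
        if len(rows) >= 3 and np.ptp(comparison["f_t1"].to_numpy()) > 0:
            x = 100.0 * comparison["f_t1"].to_numpy()
            trends = []
            for metric in ("measured_delta_ad_core", "measured_delta_rd_core"):
                tl = model.cohort_trendline(x, comparison[metric].to_numpy())
                trends.append(
                    {"metric": metric, "slope_per_percent": tl.slope,
                     "intercept": tl.intercept, "r": tl.r, "n": tl.n}
                )
            pd.DataFrame(trends).to_csv(out / "trendlines.csv", index=False)

    provenance = {
        "package": "lesionprof",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_sha256": config.digest(),
        "n_pairs": len(pair_profiles),
        "n_lesions": len(lesion_profiles),
        "n_discards": len(all_discards),
    }
    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump(provenance, fh, sort_keys=True)
    return out


@dataclass
class ValidationReport:
    entries: list[dict]

    @property
    def ok(self) -> bool:
        return all(e["status"] != "fail" for e in self.entries)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Report-only sanity checks: grid/affine consistency, diffusivity
    units plausibility (AD expected within 0.1–4 μm²/ms), mask overlap."""
    entries: list[dict] = []

    def add(check: str, status: str, message: str = "") -> None:
        entries.append({"check": check, "status": status, "message": message})

    paths = {
        "ad": config.ad_path, "rd": config.rd_path, "t1": config.t1_path,
        "lesion_mask": config.lesion_mask_path,
    }
    vols: dict[str, ScalarVolume] = {}
    for name, path in paths.items():
        if not path:
            add(f"{name} path", "warn", "not provided")
            continue
        try:
            vols[name] = load_volume(path)
            add(f"{name} path", "pass", path)
        except Exception as exc:  # noqa: BLE001
            add(f"{name} path", "fail", str(exc))
    if "ad" in vols:
        ref = vols["ad"]
        for name, vol in vols.items():
            if vol.shape != ref.shape or not np.allclose(
                vol.affine, ref.affine, atol=1e-6
            ):
                add("co-registration", "fail", f"{name} grid/affine differs from ad")
                break
        else:
            add("co-registration", "pass", "all volumes share one grid and affine")
        wm_vals = np.asarray(ref.data, dtype=float)
        wm_vals = wm_vals[np.isfinite(wm_vals) & (wm_vals > 0)]
        if wm_vals.size:
            med = float(np.median(wm_vals))
            if 0.1 <= med <= 4.0:
                add("AD units", "pass", f"median {med:.3g} μm²/ms")
            else:
                add(
                    "AD units", "warn",
                    f"median {med:.3g} outside 0.1–4 μm²/ms; check unit scale",
                )
        if "lesion_mask" in vols:
            lesion = np.asarray(vols["lesion_mask"].data) > 0
            if lesion.shape != ref.shape:
                add("lesion mask grid", "fail", "lesion mask is off-grid")
            elif not lesion.any():
                add("lesion mask", "warn", "lesion mask is empty")
            else:
                add("lesion mask", "pass", f"{int(lesion.sum())} lesional voxels")
    return ValidationReport(entries=entries)
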