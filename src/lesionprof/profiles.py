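"""13-point diffusivity asymmetry profiles and their aggregation.

Each lesional/non-lesional fiber pair yields a 13-position profile: five
extra-lesional points per side (1–5 mm from the lesion), one rim point per
side, and a single pooled lesion-core point.  The asymmetry ΔX at a
position is the lesional value minus the matched non-lesional reference.
Profiles are averaged over fibers within a lesion, then over lesions
(weighted by fiber count) to a patient profile, whose two sides are
finally averaged into the 7-point personalised lesional diffusivity (PLD)
profile: core, rim, 1–5 mm.

MD-based crossing-fiber normalisation: incoherent crossing fibers lower AD
and raise RD while leaving MD = (AD + 2·RD)/3 unchanged, whereas pathology
(axonal loss, demyelination) raises MD.  The extra-lesional baseline of a
pair's ΔAD/ΔRD profile is therefore linearly fitted and its MD-preserving
component (the direction δAD = −2·δRD) projected out; the MD-raising part
of the profile is untouched.  This reconstruction of the correction can be
switched off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matching import CORE, RIM_MINUS, RIM_PLUS, Discard, FiberPair
from .volumes import DiffusivityMaps

__all__ = [
    "POSITIONS",
    "POSITION_X_MM",
    "PLD_POSITIONS",
    "PairProfile",
    "LesionProfile",
    "PatientProfile",
    "build_pair_profile",
    "md_normalize",
    "aggregate_lesion",
    "aggregate_patient",
    "profile_summary",
]

#: the 13 profile positions, proximal flank → core → distal flank
POSITIONS: tuple[str, ...] = (
    "-5mm", "-4mm", "-3mm", "-2mm", "-1mm",
    "rim-", "core", "rim+",
    "+1mm", "+2mm", "+3mm", "+4mm", "+5mm",
)
#: nominal arc coordinate of each position (mm, core at 0; rim at ±0.5)
POSITION_X_MM = np.array(
    [-5.0, -4.0, -3.0, -2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0]
)
_FLANK_IDX = np.array([0, 1, 2, 3, 4, 8, 9, 10, 11, 12])
_CORE_IDX = 6
_ZONE_OF_POSITION = {
    "-5mm": "-5", "-4mm": "-4", "-3mm": "-3", "-2mm": "-2", "-1mm": "-1",
    "rim-": RIM_MINUS, "core": CORE, "rim+": RIM_PLUS,
    "+1mm": "+1", "+2mm": "+2", "+3mm": "+3", "+4mm": "+4", "+5mm": "+5",
}

PLD_POSITIONS: tuple[str, ...] = ("core", "rim", "1mm", "2mm", "3mm", "4mm", "5mm")


def _check13(*arrays: np.ndarray) -> None:
    for a in arrays:
        if a.shape != (13,):
            raise ValueError("profile arrays must have exactly 13 positions")


@dataclass
class PairProfile:
    """13-point AD/RD profile of one lesional/non-lesional fiber pair."""

    ad_lesional: np.ndarray
    rd_lesional: np.ndarray
    ad_reference: np.ndarray
    rd_reference: np.ndarray
    delta_ad: np.ndarray
    delta_rd: np.ndarray
    delta_md: np.ndarray
    n_core_samples: int
    n_matches: int
    tract_name: str = ""
    lesion_id: int = 0
    fiber_index: int = -1
    md_normalized: bool = False
    normalization_skipped: bool = False

    def __post_init__(self) -> None:
        _check13(
            self.ad_lesional, self.rd_lesional, self.ad_reference,
            self.rd_reference, self.delta_ad, self.delta_rd, self.delta_md,
        )

    def is_finite(self) -> bool:
        return bool(
            np.all(np.isfinite(self.delta_ad)) and np.all(np.isfinite(self.delta_rd))
        )


@dataclass
class LesionProfile:
    """Per-lesion mean of the contributing pair profiles (unweighted)."""

    delta_ad: np.ndarray
    delta_rd: np.ndarray
    delta_md: np.ndarray
    ad_lesional: np.ndarray
    rd_lesional: np.ndarray
    ad_reference: np.ndarray
    rd_reference: np.ndarray
    n_fibers: int
    lesion_id: int = 0

    def __post_init__(self) -> None:
        _check13(self.delta_ad, self.delta_rd, self.delta_md)
        if self.n_fibers < 1:
            raise ValueError("a lesion profile needs at least one fiber")


@dataclass
class PatientProfile:
    """Fiber-count-weighted patient asymmetry profile and its symmetrized
    7-point PLD form."""

    asym_delta_ad: np.ndarray
    asym_delta_rd: np.ndarray
    pld_delta_ad: np.ndarray
    pld_delta_rd: np.ndarray
    weights: dict[int, float] = field(default_factory=dict)
    n_lesions: int = 0
    n_fibers: int = 0


def build_pair_profile(
    pair: FiberPair, maps: DiffusivityMaps, mode: str = "nearest"
) -> PairProfile | Discard:
    """Sample the diffusivity maps along a fiber pair and reduce to the 13
    positions.

    Core and rim values pool all samples of that zone; the reference value
    at a position is the mean over index-corresponding samples of all
    matched fibers.  Pairs with samples outside the map grid are discarded.
    """
    zoned = pair.lesional
    ad_l = maps.ad.sample(zoned.points, mode=mode)
    rd_l = maps.rd.sample(zoned.points, mode=mode)
    match_pts = np.asarray(pair.matches)  # (M, N, 3)
    flat = match_pts.reshape(-1, 3)
    ad_m = maps.ad.sample(flat, mode=mode).reshape(match_pts.shape[:2])
    rd_m = maps.rd.sample(flat, mode=mode).reshape(match_pts.shape[:2])
    if not (
        np.all(np.isfinite(ad_l))
        and np.all(np.isfinite(rd_l))
        and np.all(np.isfinite(ad_m))
        and np.all(np.isfinite(rd_m))
    ):
        return Discard(zoned.fiber_index, zoned.tract_name, "samples outside grid")
    ad_ref = ad_m.mean(axis=0)  # per-sample mean across matched fibers
    rd_ref = rd_m.mean(axis=0)

    def reduce(values: np.ndarray) -> np.ndarray:
        out = np.full(13, np.nan)
        for i, pos in enumerate(POSITIONS):
            idx = zoned.zone_indices(_ZONE_OF_POSITION[pos])
            if idx.size:
                out[i] = values[idx].mean()
        return out

    ad_les13, rd_les13 = reduce(ad_l), reduce(rd_l)
    ad_ref13, rd_ref13 = reduce(ad_ref), reduce(rd_ref)
    if not np.all(np.isfinite(ad_les13)):
        return Discard(zoned.fiber_index, zoned.tract_name, "missing profile position")
    d_ad = ad_les13 - ad_ref13
    d_rd = rd_les13 - rd_ref13
    return PairProfile(
        ad_lesional=ad_les13,
        rd_lesional=rd_les13,
        ad_reference=ad_ref13,
        rd_reference=rd_ref13,
        delta_ad=d_ad,
        delta_rd=d_rd,
        delta_md=(d_ad + 2.0 * d_rd) / 3.0,
        n_core_samples=int(zoned.zone_indices(CORE).size),
        n_matches=pair.n_matches,
        tract_name=zoned.tract_name,
        lesion_id=zoned.lesion_id,
        fiber_index=zoned.fiber_index,
    )


def md_normalize(profile: PairProfile, min_finite: int = 4) -> PairProfile:
    """Project the MD-preserving (crossing-fiber) component out of a pair
    profile's extra-lesional baseline.

    Straight lines are fitted to ΔAD and ΔRD over the ten extra-lesional
    positions.  The fitted baseline is decomposed at every position into an
    MD-preserving part (δAD, δRD) = (−2g, g) — the signature of fiber
    incoherence — and an MD-raising remainder; only the former is
    subtracted:

        g(x) = (2·ΔAD_fit(x) − ΔRD_fit(x)) / 5
        ΔAD ← ΔAD − 2·g(x),   ΔRD ← ΔRD + g(x)

    The subtracted component has (δAD + 2·δRD)/3 ≡ 0, so ΔMD is unchanged,
    and refitting the corrected baseline yields g ≡ 0, making the operation
    idempotent.  Profiles with fewer than ``min_finite`` finite
    extra-lesional points are passed through with a flag.
    """
    d_ad = profile.delta_ad
    d_rd = profile.delta_rd
    x = POSITION_X_MM[_FLANK_IDX]
    ya, yr = d_ad[_FLANK_IDX], d_rd[_FLANK_IDX]
    finite = np.isfinite(ya) & np.isfinite(yr)
    if finite.sum() < min_finite:
        warnings.warn(
            "too few finite extra-lesional points; profile not normalized",
            stacklevel=2,
        )
        return replace(profile, normalization_skipped=True)
    fit_ad = np.polynomial.Polynomial.fit(x[finite], ya[finite], 1)
    fit_rd = np.polynomial.Polynomial.fit(x[finite], yr[finite], 1)
    g = (2.0 * fit_ad(POSITION_X_MM) - fit_rd(POSITION_X_MM)) / 5.0
    new_ad = d_ad - 2.0 * g
    new_rd = d_rd + g
    return replace(
        profile,
        delta_ad=new_ad,
        delta_rd=new_rd,
        delta_md=(new_ad + 2.0 * new_rd) / 3.0,
        md_normalized=True,
    )


def aggregate_lesion(pair_profiles: list[PairProfile]) -> LesionProfile:
    """Unweighted per-position mean over all fiber pairs of one lesion."""
    profiles = [p for p in pair_profiles if p.is_finite()]
    if not profiles:
        raise ValueError("no finite pair profiles to aggregate")
    stack = lambda attr: np.mean([getattr(p, attr) for p in profiles], axis=0)
    return LesionProfile(
        delta_ad=stack("delta_ad"),
        delta_rd=stack("delta_rd"),
        delta_md=stack("delta_md"),
        ad_lesional=stack("ad_lesional"),
        rd_lesional=stack("rd_lesional"),
        ad_reference=stack("ad_reference"),
        rd_reference=stack("rd_reference"),
        n_fibers=len(profiles),
        lesion_id=profiles[0].lesion_id,
    )


def symmetrize(values13: np.ndarray) -> np.ndarray:
    """Average positions equally removed from the core: 13 → 7 points
    (core, rim, 1–5 mm)."""
    v = np.asarray(values13, dtype=float)
    _check13(v)
    out = np.empty(7)
    out[0] = v[_CORE_IDX]
    out[1] = 0.5 * (v[5] + v[7])
    for k in range(1, 6):
        out[1 + k] = 0.5 * (v[5 - k] + v[7 + k])
    return out


def aggregate_patient(lesion_profiles: list[LesionProfile]) -> PatientProfile:
    """Fiber-count-weighted average over lesions, then left/right
    symmetrization to the 7-point PLD profile."""
    if not lesion_profiles:
        raise ValueError("no lesion profiles to aggregate")
    counts = np.array([lp.n_fibers for lp in lesion_profiles], dtype=float)
    weights = counts / counts.sum()
    asym_ad = np.einsum("l,lp->p", weights, [lp.delta_ad for lp in lesion_profiles])
    asym_rd = np.einsum("l,lp->p", weights, [lp.delta_rd for lp in lesion_profiles])
    return PatientProfile(
        asym_delta_ad=asym_ad,
        asym_delta_rd=asym_rd,
        pld_delta_ad=symmetrize(asym_ad),
        pld_delta_rd=symmetrize(asym_rd),
        weights={lp.lesion_id: float(w) for lp, w in zip(lesion_profiles, weights)},
        n_lesions=len(lesion_profiles),
        n_fibers=int(counts.sum()),
    )


def profile_summary(patients: list[PatientProfile]) -> pd.DataFrame:
    """Cohort table over the PLD profile: per-position mean ± SD of ΔAD,
    ΔRD and the per-patient ΔAD/ΔRD ratio.

    SD is reported as 0 with ``sd_defined = False`` for a single patient.
    """
    if not patients:
        raise ValueError("no patients")
    ad = np.array([p.pld_delta_ad for p in patients])
    rd = np.array([p.pld_delta_rd for p in patients])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rd != 0, ad / rd, np.nan)
    n = len(patients)

    def sd(a: np.ndarray) -> np.ndarray:
        return np.zeros(a.shape[1]) if n == 1 else np.nanstd(a, axis=0, ddof=1)

    with warnings.catch_warnings():
        # positions where every patient has ΔRD = 0 yield an all-NaN ratio
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return pd.DataFrame(
            {
                "position": PLD_POSITIONS,
                "delta_ad_mean": np.nanmean(ad, axis=0),
                "delta_ad_sd": sd(ad),
                "delta_rd_mean": np.nanmean(rd, axis=0),
                "delta_rd_sd": sd(rd),
                "ad_rd_ratio_mean": np.nanmean(ratio, axis=0),
                "ad_rd_ratio_sd": sd(ratio),
                "n_patients": n,
                "sd_defined": n > 1,
            }
        )


def pair_table(profiles: list[PairProfile]) -> pd.DataFrame:
    """Tidy per-pair table (one row per position and metric)."""
    rows = []
    for p in profiles:
        for i, pos in enumerate(POSITIONS):
            for metric, arr in (
                ("delta_ad", p.delta_ad),
                ("delta_rd", p.delta_rd),
                ("delta_md", p.delta_md),
            ):
                rows.append(
                    {
                        "tract": p.tract_name,
                        "lesion_id": p.lesion_id,
                        "fiber_index": p.fiber_index,
                        "position": pos,
                        "metric": metric,
                        "value": arr[i],
                        "n_matches": p.n_matches,
                    }
                )
    return pd.DataFrame(rows)


def lesion_table(profiles: list[LesionProfile]) -> pd.DataFrame:
    rows = []
    for lp in profiles:
        for i, pos in enumerate(POSITIONS):
            for metric, arr in (
                ("delta_ad", lp.delta_ad),
                ("delta_rd", lp.delta_rd),
                ("delta_md", lp.delta_md),
            ):
                rows.append(
                    {
                        "lesion_id": lp.lesion_id,
                        "position": pos,
                        "metric": metric,
                        "value": arr[i],
                        "n_fibers": lp.n_fibers,
                    }
                )
    return pd.DataFrame(rows)


def patient_table(patient: PatientProfile) -> pd.DataFrame:
    rows = []
    for i, pos in enumerate(POSITIONS):
        rows.append({"profile": "asym13", "position": pos,
                     "delta_ad": patient.asym_delta_ad[i],
                     "delta_rd": patient.asym_delta_rd[i]})
    for i, pos in enumerate(PLD_POSITIONS):
        rows.append({"profile": "pld7", "position": pos,
                     "delta_ad": patient.pld_delta_ad[i],
                     "delta_rd": patient.pld_delta_rd[i]})
    return pd.DataFrame(rows)
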