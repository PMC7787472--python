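# Methods

This note documents the models and procedures implemented in
`lesionprof`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic phantom does
and does not establish.

## Coordinate and sampling conventions

All geometry is world (RAS) millimetres; voxel indices are 0-based with
the voxel-centre convention, which removes the TRK voxel-corner ambiguity
at a single boundary (`volumes.load_tract` converts both TRK and TCK to
world mm on load). Scalar maps are sampled nearest-neighbour by default:
the profile quantities are statements about the voxels a streamline
traverses, not about interpolated values, and resampling would introduce
partial-volume mixing at lesion borders. Trilinear sampling is available
for sensitivity analyses.

## Lesional fiber selection and zoning

A streamline is *lesional* when its dense resampling (0.5 mm) touches
exactly one lesion label. Fibers touching two or more lesions are
excluded because a second lesion can drive Wallerian degeneration along
the same axon bundle; fibers touching the CSF mask dilated by one voxel,
or the grey-matter mask, are excluded because their diffusivities are not
interpretable as white-matter values.

The lesional fiber is arc-length resampled at `step_mm` (default 1 mm,
matching the millimetre spacing of the extra-lesional profile positions;
configurable) and truncated to the lesion run plus `flank_mm` = 5 mm per
side, so flank distances are measured along the fiber's arc rather than
as chords. Zones are assigned per sample from the core and rim masks.
Two degenerate cases are handled explicitly:

* a fiber whose in-lesion samples never touch the eroded core is
  discarded with reason `no core contact` — the 13-point profile requires
  a core value, and a rim-graze does not represent lesion tissue;
* when the 1-voxel rim shell falls between two successive samples on one
  side, the outermost in-lesion sample on that side is relabelled from
  core to rim, so the rim position is always populated without
  double-counting any sample. This only triggers when the shell was
  skipped by sampling.

Every discard carries a machine-readable reason and ends up in
`discards.csv`; nothing is silently dropped.

## Matching

Candidates are all streamlines of the same tract that intersect no
lesion. "Similar length and orientation" is enforced entirely
geometrically, with no separate angle threshold: a candidate must cross
both limiting planes (perpendicular to the lesional fiber at the flank
endpoints), is clipped between them, resampled to the lesional sample
count, and accepted when at least `tube_fraction` = 90 % of its samples
lie within `tube_diameter`/2 = 2.5 mm of the lesional polyline
(point-to-segment distance, so vertex spacing does not bias the test).
The tube test is evaluated after plane clipping; evaluating it before
clipping would let fiber portions far from the lesion veto otherwise
parallel neighbours. Correspondence between lesional and matched samples
is positional (index *i* ↔ index *i*) after the equal-count resampling —
the deterministic realisation of point-wise correspondence between
parallel fibers. Acceptance is per-candidate, never competitive, so
results are independent of candidate order; a bounding-box prefilter only
skips candidates that cannot intersect the tube. Fewer than
`min_matches` = 5 accepted candidates discards the lesional fiber.

## Profiles and aggregation

Per pair, the core value pools all core samples of the lesional fiber
(lesion chords vary in length; pooling makes pairs comparable), the rim
value pools each side's rim samples, and each flank position is one
sample. The reference value at a position applies the same reduction to
the per-sample mean across all matched fibers. Asymmetry is
ΔX = X_lesional − X_reference, and ΔMD ≡ (ΔAD + 2 ΔRD)/3 by construction.

Aggregation is: unweighted mean over a lesion's pairs (every analysed
fiber of a lesion counts equally), then a fiber-count-weighted mean over
lesions (adjusting for lesion size), then left/right symmetrisation into
the 7-point PLD profile (core; rim = mean of the two rim points; k mm =
mean of the −k and +k points). Weights sum to 1 and the result is
invariant to lesion ordering. Pairs with any non-finite position (e.g. a
sample outside the grid) are dropped, never imputed. The rim is kept
side-specific through the 13-point stage and only pooled by the
symmetrisation, preserving the 13-point count.

## MD-based crossing-fiber correction

The correction rests on two facts: (i) MD = (AD + 2 RD)/3 is nearly
uniform across normal white matter, while AD and RD vary strongly and in
opposite directions with local fiber coherence; (ii) a crossing-fiber
difference between a lesional sample and its reference therefore shows up
as an MD-preserving perturbation (δAD, δRD) = (−2g, g), whereas real
pathology (axonal loss, demyelination) raises MD.

The implementation fits straight lines to ΔAD and ΔRD over the ten
extra-lesional positions (linear fitting of the baseline), decomposes the
fitted baseline at every position, and subtracts only its MD-preserving
component:

```
g(x) = (2·ΔAD_fit(x) − ΔRD_fit(x)) / 5
ΔAD ← ΔAD − 2·g(x)
ΔRD ← ΔRD + g(x)
```

The coefficients come from least-squares projection of (ΔAD_fit, ΔRD_fit)
onto the direction (−2, 1). The rim positions are assigned nominal arc
coordinates ±0.5 mm and the core 0 mm for evaluating the fitted lines
inside the lesion. Consequences, all tested: a pure contamination
baseline (ΔAD = −2 ΔRD) is removed exactly; an MD-raising baseline
(ΔAD = ΔRD = c) loses only its projection (ΔAD → 3c/5, ΔRD → 6c/5); ΔMD
is bit-for-bit unchanged; and the operation is idempotent, because
refitting a corrected baseline gives g ≡ 0. This correction is a
principled reconstruction of the idea rather than a port of any
particular implementation, and can be disabled
(`md_normalize: false` in the run config), in which case profiles pass
through untouched. Profiles with fewer than four finite extra-lesional
points are passed through with a flag. An alternative policy — discarding
contaminated pairs instead of correcting them — can be emulated by
disabling the correction and filtering on the pair table's baseline
slopes.

## T1-derived axonal loss

T1 hypointensity tracks axonal destruction. With I_NAWM the mean
intensity over the supplied normal-appearing-white-matter ROIs (intact
tissue, f = 0) and I_CSF the *minimum* intensity over the CSF ROIs
(tissue devoid of axons, f = 1), the axonal-loss fraction of a lesion is

```
f = (I_NAWM − mean I_lesion) / (I_NAWM − I_CSF),  clipped to [0, 1]
```

computed only over lesional voxels traversed by analysed lesional fibers;
voxels without streamlines skew destructive and are not part of the
streamline analysis. Clipping is needed because noise can push the linear
estimate outside the physical range. The patient value weights lesions by
fiber count (falling back to analysed-voxel count when no counts are
supplied). Lesions with no fiber-intersected voxels are excluded with a
warning. `compare_voxel_subsets` quantifies the selection effect by
comparing the mean T1 reduction in analysed vs remaining lesional voxels,
returning both raw and NAWM-normalised reductions (the normalisation
convention for the relative difference is not uniquely determined, so
both are reported).

Erosion for the core/rim split uses a 6-connected (faces-only)
structuring element — the minimal reading of "shrink by one voxel in all
directions" — with 18- and 26-connectivity available via configuration.
The lesion size filter is strict: a lesion must exceed 100 mm³, so a
100-voxel lesion at 1 mm³ voxels is removed.

## The two-compartment forward model

Lesion-core diffusivity change is modelled as axonal tissue being
replaced by extra-cellular water plus demyelination of the survivors:

```
ΔAD(f)    = f·(AD_axloss − AD_normal)
ΔRD(f, m) = m·k_dem·(1 − f) + f·(RD_axloss − RD_normal)
```

| parameter  | default | units  | meaning |
|------------|--------:|--------|---------|
| AD_normal  | 1.22    | μm²/ms | AD of coherent normal white matter |
| RD_normal  | 0.59    | μm²/ms | RD of coherent normal white matter |
| AD_axloss  | 2.5     | μm²/ms | AD ceiling at complete axonal loss |
| RD_axloss  | 1.7     | μm²/ms | RD ceiling at complete axonal loss |
| k_dem      | 0.20    | μm²/ms | RD increase from full demyelination of intact tissue |

The ceilings fall short of free water (≈ 3 μm²/ms) because gliosis and
axonal tortuosity keep diffusion partially restricted even in destroyed
tissue; no explicit gliosis term is modelled, so measured values are
expected to fall below the model line at high f. k_dem = 0.20 is the
default; 0.23 (an optic-radiation estimate) is a documented alternative.
`m`, the demyelinated fraction of surviving axons, defaults to 1 —
chronic lesions are assumed fully demyelinated — but is exposed so the
dual-driver structure is testable. Both maps are affine in f; ΔRD
dominates below the crossing point f = 0.2/0.37 ≈ 0.54 (defaults), after
which ΔAD leads.

Inversion is algebraic: f̂ = ΔAD/(AD_axloss − AD_normal), then
m̂ = (ΔRD − f̂·(RD_axloss − RD_normal)) / (k_dem·(1 − f̂)), both clipped to
[0, 1]. m̂ is undefined at f̂ = 1 (no survivors) and flagged unreliable for
f̂ > 0.6, where the demyelination term is a small residual of a large
subtraction. f is a fraction internally; reporting layers multiply by 100
to match the percent convention of cohort plots. Trendlines
(`cohort_trendline`) are ordinary least squares with intercept plus
Pearson r; on model-generated cohorts the ΔAD intercept is 0 and the ΔRD
intercept is k_dem to machine precision.

## The phantom

`phantom.generate_phantom` builds piecewise-homogeneous tissue: white
matter at (AD, RD) = (1.22, 0.59) μm²/ms, a CSF slab at 3.0 (free water)
with T1 = 863, a grey-matter slab at 0.8 with T1 = 0.75·I_NAWM, and
ellipsoidal lesions whose diffusivities come from the forward model at
known (f, m) and whose T1 is I_NAWM − f·(I_NAWM − I_CSF) with anchors
I_NAWM = 3326 and I_CSF = 863 (cohort-average values, which makes
recovery tests self-documenting). MD is always recomputed from the
identity, including after the optional i.i.d. Gaussian noise on AD and RD
(the simplest noise model that preserves the identity). Streamlines are
analytic: each is the bundle centerline shifted by a constant lateral
offset drawn uniformly over the disk cross-section — tract segmentation
and tractography are out of scope, and matching only needs geometry. The
default of 2000 streamlines per tract matches standard per-tract
tractogram density; the test suite uses 150–300 to keep runtimes low,
which changes counting statistics but no geometric decision.
`add_crossing_contamination` perturbs (AD, RD) by (−2δ, +δ) in a region,
the MD-preserving signature of incoherent crossings, and refuses
perturbations that would order RD above AD.

What the phantom does *not* emulate, and what passing tests therefore do
not show: partial-volume gradients at lesion borders (lesions are
internally homogeneous, so phantom rim values equal core values, unlike
real lesions), curved or kissing bundles, spatially correlated noise,
Wallerian AD elevation along the distal fiber, and realistic DWI signal
formation (no b-values, gradients or tensor fitting — maps are generated
directly). Parameter-recovery results on phantoms demonstrate the
correctness of the computational chain, not the biological validity of
the model constants.

## Determinism and provenance

All randomness flows through one integer seed
(`numpy.random.default_rng`). Pipeline reruns with an identical config
and seed produce byte-identical CSVs (no timestamps are written), and
every output directory carries a provenance record with the package
version, seed, full config and its SHA-256 hash. All thresholds live in
the single `RunConfig`/YAML record; there are no hidden numeric defaults
in code paths.

## Known limitations

* Centrally located voxels of large lesions are under-sampled: a fiber
  deep inside a big lesion rarely has non-lesional neighbours within the
  2.5 mm tube, so estimates are biased toward lesion portions with
  preserved axons (this mirrors the streamline-availability bias of the
  T1 estimate, which is why the fiber-intersected voxel restriction
  matters).
* The 1 mm resampling step is an inference from the millimetre profile
  grid, not a uniquely determined value; it is configurable
  (`step_mm`).
* The MD-based correction assumes contamination is linear along the
  10-point baseline; strongly non-linear coherence changes within 5 mm
  are only partially removed.
* No gliosis correction: at high f the forward model over-predicts
  measured diffusivity increases by design.
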