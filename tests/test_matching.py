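"""Lesional fiber selection, truncation/zoning and non-lesional matching."""

import numpy as np
import pytest

from conftest import rigid_transform
from lesionprof import matching
from lesionprof.lesions import LesionMaskSet
from lesionprof.matching import (
    CORE,
    RIM_MINUS,
    RIM_PLUS,
    Discard,
    FiberPair,
    build_fiber_pairs,
    find_lesional_fibers,
    match_nonlesional,
    truncate_and_zone,
)
from lesionprof.volumes import Tract


def straight_fiber(x0=-10.0, x1=28.0, y=9.0, z=9.0, n=2):
    return np.array([[x0, y, z], [x1, y, z]])[: max(n, 2)]


@pytest.fixture
def box_lesion_scene():
    """Box lesion spanning voxels x 5..13 in an 19³-ish grid; its 1-voxel
    erosion core spans x 6..12 (7 voxels) in the y/z interior."""
    labels = np.zeros((24, 19, 19), dtype=np.int32)
    labels[5:14, 5:14, 5:14] = 1
    return LesionMaskSet(labels=labels, affine=np.eye(4))


class TestFindLesionalFibers:
    def _tract(self, fibers):
        return Tract(name="t", streamlines=fibers)

    def test_single_lesion_fiber_kept(self, box_lesion_scene):
        sel = find_lesional_fibers(
            self._tract([straight_fiber()]), box_lesion_scene
        )
        assert sel.lesional == [(0, 1)]

    def test_fiber_missing_lesion_is_candidate(self, box_lesion_scene):
        sel = find_lesional_fibers(
            self._tract([straight_fiber(y=2.0, z=2.0)]), box_lesion_scene
        )
        assert sel.nonlesional_indices == [0]

    def test_two_lesion_fiber_excluded(self, box_lesion_scene):
        labels = box_lesion_scene.labels.copy()
        labels[16:20, 5:14, 5:14] = 2
        scene = LesionMaskSet(labels=labels, affine=np.eye(4))
        sel = find_lesional_fibers(self._tract([straight_fiber()]), scene)
        assert sel.lesional == []
        assert sel.excluded[0].reason == "intersects multiple lesions"

    def test_fiber_grazing_dilated_csf_excluded(self, box_lesion_scene):
        csf = np.zeros(box_lesion_scene.labels.shape, dtype=bool)
        csf[:, 0:2, :] = True  # raw CSF at y 0..1; 1-voxel dilation adds y=2
        labels = box_lesion_scene.labels.copy()
        labels[5:14, 2:14, 5:14] = 1  # lesion reaches the dilation ring
        fiber = straight_fiber(y=2.0, z=9.0)  # grazes y=2: dilated CSF only
        sel = find_lesional_fibers(
            self._tract([fiber]),
            LesionMaskSet(labels=labels, affine=np.eye(4)),
            csf_mask=csf,
        )
        assert sel.lesional == []
        assert sel.excluded[0].reason == "intersects dilated CSF"
        # without the CSF mask the same fiber is lesional
        sel2 = find_lesional_fibers(
            self._tract([fiber]), LesionMaskSet(labels=labels, affine=np.eye(4))
        )
        assert sel2.lesional == [(0, 1)]

    def test_gm_fiber_excluded(self, box_lesion_scene):
        gm = np.zeros(box_lesion_scene.labels.shape, dtype=bool)
        gm[:, 9, :] = True
        sel = find_lesional_fibers(
            self._tract([straight_fiber()]), box_lesion_scene, gm_mask=gm
        )
        assert sel.lesional == []
        assert sel.excluded[0].reason == "intersects grey matter"


class TestTruncateAndZone:
    def test_straight_chord_zoning(self, box_lesion_scene):
        """A straight fiber through a 7-voxel core chord: 7 core samples,
        one rim sample per side, exactly 5 flank samples per side."""
        zoned = truncate_and_zone(
            straight_fiber(x0=-10.0, x1=28.0),
            box_lesion_scene.core_mask(1),
            box_lesion_scene.rim_mask(1),
            np.eye(4),
        )
        assert isinstance(zoned, matching.ZonedFiber)
        zones = list(zoned.zones)
        assert zones.count(CORE) == 7
        assert zones.count(RIM_MINUS) == 1
        assert zones.count(RIM_PLUS) == 1
        for k in range(1, 6):
            assert zones.count(f"-{k}") == 1
            assert zones.count(f"+{k}") == 1
        assert zoned.n_samples == 19
        # planes sit at the flank endpoints with tangent normals
        assert np.allclose(zoned.planes.normal_start, [1, 0, 0], atol=1e-9)
        assert np.allclose(zoned.planes.point_start, zoned.points[0])

    def test_rim_only_fiber_discarded(self, box_lesion_scene):
        # fiber at the lesion face: touches rim voxels but no eroded core
        result = truncate_and_zone(
            straight_fiber(y=5.0, z=9.0),
            box_lesion_scene.core_mask(1),
            box_lesion_scene.rim_mask(1),
            np.eye(4),
        )
        assert isinstance(result, Discard)
        assert result.reason == "no core contact"

    def test_missing_flank_room_discarded(self, box_lesion_scene):
        result = truncate_and_zone(
            straight_fiber(x0=3.0, x1=28.0),  # only ~2 mm before the lesion
            box_lesion_scene.core_mask(1),
            box_lesion_scene.rim_mask(1),
            np.eye(4),
        )
        assert isinstance(result, Discard)
        assert result.reason == "insufficient flank"

    def test_curved_fiber_flank_measured_along_arc(self):
        """On a circular fiber the 5 mm flank is 5 mm of *arc*, so its
        chord length is strictly shorter."""
        radius = 12.0
        center = np.array([20.0, 20.0, 9.0])
        theta = np.linspace(-1.2, 1.2, 600)
        fiber = center + np.stack(
            [radius * np.sin(theta), -radius * np.cos(theta), 0 * theta], axis=1
        )
        labels = np.zeros((40, 40, 19), dtype=np.int32)
        # lesion blob around the arc's lowest point
        ii, jj, kk = np.indices(labels.shape)
        blob = (ii - 20) ** 2 + (jj - 8) ** 2 + (kk - 9) ** 2 <= 3.0**2
        labels[blob] = 1
        scene = LesionMaskSet(labels=labels, affine=np.eye(4))
        zoned = truncate_and_zone(
            fiber, scene.core_mask(1), scene.rim_mask(1), np.eye(4)
        )
        assert isinstance(zoned, matching.ZonedFiber)
        idx0 = int(np.flatnonzero(zoned.zones == "-5")[0])
        idx1 = int(np.flatnonzero(zoned.zones == RIM_MINUS)[0])
        arc = np.linalg.norm(
            np.diff(zoned.points[idx0 : idx1 + 1], axis=0), axis=1
        ).sum()
        chord = np.linalg.norm(zoned.points[idx1] - zoned.points[idx0])
        # chordal resampling underestimates the true arc by O(step²/R²)
        assert arc == pytest.approx(5.0, abs=5e-3)
        # analytic oracle: a 5 mm arc on a 12 mm circle has a 4.964 mm chord
        expected_chord = 2 * 12.0 * np.sin(5.0 / (2 * 12.0))
        assert chord == pytest.approx(expected_chord, abs=0.02)
        assert chord < arc


class TestMatchNonlesional:
    @pytest.fixture
    def zoned(self, box_lesion_scene):
        return truncate_and_zone(
            straight_fiber(),
            box_lesion_scene.core_mask(1),
            box_lesion_scene.rim_mask(1),
            np.eye(4),
        )

    def _parallel(self, dy, dz=0.0, x0=-12.0, x1=30.0):
        pts = np.linspace([x0, 9.0 + dy, 9.0 + dz], [x1, 9.0 + dy, 9.0 + dz], 60)
        return pts

    def test_close_parallel_candidates_accepted(self, zoned):
        cands = [self._parallel(1.0), self._parallel(-1.0), self._parallel(0.5, 1.0),
                 self._parallel(-0.5, -1.0), self._parallel(2.0)]
        pair = match_nonlesional(zoned, cands)
        assert isinstance(pair, FiberPair)
        assert pair.n_matches == 5
        for m in pair.matches:
            assert m.shape == (zoned.n_samples, 3)

    def test_far_candidate_rejected(self, zoned):
        cands = [self._parallel(1.0)] * 4 + [self._parallel(4.0)]
        result = match_nonlesional(zoned, cands)
        assert isinstance(result, Discard)
        assert "insufficient matches (4 < 5)" in result.reason

    def test_four_matches_insufficient(self, zoned):
        result = match_nonlesional(zoned, [self._parallel(1.0)] * 4)
        assert isinstance(result, Discard)

    def test_candidate_not_reaching_planes_rejected(self, zoned):
        short = np.linspace([5.0, 10.0, 9.0], [10.0, 10.0, 9.0], 10)
        result = match_nonlesional(zoned, [short] * 6)
        assert isinstance(result, Discard)

    def test_reversed_candidates_still_match(self, zoned):
        cands = [self._parallel(1.0)[::-1] for _ in range(5)]
        pair = match_nonlesional(zoned, cands)
        assert isinstance(pair, FiberPair)
        # orientation is aligned with the lesional fiber before clipping
        for m in pair.matches:
            assert m[-1, 0] > m[0, 0]

    def test_acceptance_independent_of_candidate_order(self, zoned):
        cands = [self._parallel(d) for d in (-2.0, -1.0, 0.5, 1.0, 1.5, 4.0)]
        a = match_nonlesional(zoned, cands, candidate_indices=list(range(6)))
        b = match_nonlesional(
            zoned, cands[::-1], candidate_indices=list(range(6))[::-1]
        )
        assert isinstance(a, FiberPair) and isinstance(b, FiberPair)
        assert sorted(a.match_indices) == sorted(b.match_indices)


class TestPhantomMatching:
    def test_pair_congruence(self, fiber_pairs):
        """Lesional and matched polylines have identical sample counts and
        arc spacing within one step."""
        pairs, _ = fiber_pairs
        for pair in pairs:
            n = pair.lesional.n_samples
            step = pair.lesional.step
            assert pair.n_matches >= 5
            for m in pair.matches:
                assert m.shape == (n, 3)
                seg = np.linalg.norm(np.diff(m, axis=0), axis=1)
                assert np.all(np.abs(seg - step) < step)

    def test_tube_strictness_monotonicity(self, phantom_data):
        """Tightening the tube constraint never yields more pairs."""
        counts = []
        for diameter in (6.0, 5.0, 3.0, 1.5):
            pairs, _ = build_fiber_pairs(
                phantom_data.tracts[0],
                phantom_data.lesions,
                csf_mask=phantom_data.tissues.csf,
                gm_mask=phantom_data.tissues.gm,
                tube_diameter=diameter,
            )
            counts.append(len(pairs))
        assert counts == sorted(counts, reverse=True)

    def test_rigid_transform_invariance(self, phantom_data):
        """Rigidly moving the whole scene changes no acceptance decision."""
        transform = rigid_transform(17.0, axis=2, translation=[5.0, -3.0, 2.0])
        rot, shift = transform[:3, :3], transform[:3, 3]

        base_pairs, base_discards = build_fiber_pairs(
            phantom_data.tracts[0], phantom_data.lesions,
            csf_mask=phantom_data.tissues.csf, gm_mask=phantom_data.tissues.gm,
        )
        moved_tract = Tract(
            name="moved",
            streamlines=[s @ rot.T + shift for s in phantom_data.tracts[0].streamlines],
        )
        moved_lesions = LesionMaskSet(
            labels=phantom_data.lesions.labels,
            affine=transform @ phantom_data.lesions.affine,
        )
        moved_pairs, moved_discards = build_fiber_pairs(
            moved_tract, moved_lesions,
            csf_mask=phantom_data.tissues.csf, gm_mask=phantom_data.tissues.gm,
        )
        assert len(moved_pairs) == len(base_pairs)
        assert [p.lesional.fiber_index for p in moved_pairs] == [
            p.lesional.fiber_index for p in base_pairs
        ]
        assert len(moved_discards) == len(base_discards)
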