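import numpy as np
import pytest

from oracles import strict_minima_oracle, suppression_oracle
from tomopick.detect import (
    DetectParams,
    detect_candidates_2r,
    detect_candidates_4r,
    exclude_masked,
    filter_subvolume_side,
    find_local_minima,
    reject_boundary,
    restrict_slab,
    suppress_close_candidates,
)
from tomopick.io import Tomogram
from tomopick.particles import STATUS_CANDIDATE, STATUS_REJECTED_MASK, STATUS_REJECTED_SLAB
from tomopick.synth import _paint_sphere


def _tomo(arr, ps=2.0):
    return Tomogram(np.asarray(arr, dtype=np.float32), pixel_size=ps)


class TestFindLocalMinima:
    def test_single_impulse_is_only_candidate(self):
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = -1.0
        cands = find_local_minima(_tomo(vol), h=5)
        assert [c.position for c in cands] == [(4, 4, 4)]
        assert cands[0].density == -1.0

    def test_constant_volume_has_no_strict_minima(self):
        assert find_local_minima(_tomo(np.ones((8, 8, 8))), h=3) == []

    def test_plateau_tie_produces_no_candidate(self):
        vol = np.ones((9, 9, 9))
        vol[4, 4, 4] = vol[4, 4, 5] = -1.0  # two tied dark voxels side by side
        assert find_local_minima(_tomo(vol), h=5) == []

    @pytest.mark.parametrize("h", [3, 5, 9])
    def test_matches_exhaustive_oracle(self, rng, h):
        vol = rng.normal(size=(24, 24, 24))
        got = {c.position for c in find_local_minima(_tomo(vol), h=h)}
        assert got == strict_minima_oracle(vol, h)

    def test_h_below_3_rejected(self):
        with pytest.raises(ValueError):
            find_local_minima(_tomo(np.zeros((8, 8, 8))), h=2)

    def test_oversized_window_reduces_to_global_minimum(self, rng, caplog):
        vol = rng.normal(size=(10, 10, 10))
        with caplog.at_level("WARNING"):
            cands = find_local_minima(_tomo(vol), h=41)
        z, y, x = np.unravel_index(np.argmin(vol), vol.shape)
        assert [c.position for c in cands] == [(int(x), int(y), int(z))]


class Test4rMode:
    def test_two_well_separated_spheres_both_found(self):
        r = 4
        vol = np.zeros((48, 48, 48))
        _paint_sphere(vol, (24, 24, 12), r, -1.0)
        _paint_sphere(vol, (24, 24, 12 + 5 * r), r, -1.0)  # 5r apart
        cands = detect_candidates_4r(_tomo(vol, ps=1.0), DetectParams(radius_angstrom=r))
        assert {c.position for c in cands} == {(12, 24, 24), (32, 24, 24)}

    def test_hard_spheres_3r_apart_yield_at_most_one(self):
        # equal-depth hard spheres 3r apart: each center's +-2r window reaches
        # the other sphere's surface, whose value ties the center -> no strict
        # minimum survives at either
        r = 4
        vol = np.zeros((48, 48, 48))
        zz, yy, xx = np.mgrid[0:48, 0:48, 0:48]
        for cx in (16, 16 + 3 * r):
            d2 = (zz - 24) ** 2 + (yy - 24) ** 2 + (xx - cx) ** 2
            vol[d2 <= r * r] = -1.0
        cands = detect_candidates_4r(_tomo(vol, ps=1.0), DetectParams(radius_angstrom=r))
        assert len(cands) <= 1

    def test_sorted_darkest_first(self, rng):
        vol = rng.normal(size=(30, 30, 30))
        cands = detect_candidates_4r(_tomo(vol, ps=1.0), DetectParams(radius_angstrom=3))
        densities = [c.density for c in cands]
        assert densities == sorted(densities)

    def test_chebyshev_separation_at_least_2r_plus_1(self, rng):
        r = 3
        vol = rng.normal(size=(32, 32, 32))
        cands = detect_candidates_4r(_tomo(vol, ps=1.0), DetectParams(radius_angstrom=r))
        pos = np.array([c.position for c in cands])
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                assert np.abs(pos[i] - pos[j]).max() >= 2 * r + 1


class Test2rMode:
    def test_single_sphere_matches_4r_mode(self):
        r = 4
        vol = np.zeros((40, 40, 40))
        _paint_sphere(vol, (20, 20, 20), r, -1.0)
        p = DetectParams(radius_angstrom=r)
        c2 = detect_candidates_2r(_tomo(vol, ps=1.0), p)
        c4 = detect_candidates_4r(_tomo(vol, ps=1.0), p)
        assert [c.position for c in c2] == [c.position for c in c4] == [(20, 20, 20)]

    def test_exactly_2r_apart_both_kept(self):
        # rejection uses strict <2r, so a pair at exactly 2r survives
        r = 6
        vol = np.zeros((40, 40, 40))
        vol[20, 20, 10] = -2.0
        vol[20, 20, 10 + 2 * r] = -1.0
        cands = detect_candidates_2r(_tomo(vol, ps=1.0), DetectParams(radius_angstrom=r))
        assert {c.position for c in cands} == {(10, 20, 20), (22, 20, 20)}

    def test_closer_than_2r_darkest_wins(self):
        r = 6
        vol = np.zeros((40, 40, 40))
        vol[20, 20, 10] = -2.0
        vol[20, 20, 10 + 2 * r - 1] = -1.0
        cands = detect_candidates_2r(_tomo(vol, ps=1.0), DetectParams(radius_angstrom=r))
        assert [c.position for c in cands] == [(10, 20, 20)]

    def test_crowded_volume_matches_suppression_oracle(self, rng):
        r = 3
        vol = rng.normal(size=(32, 32, 32))
        tomo = _tomo(vol, ps=1.0)
        minima = find_local_minima(tomo, 2 * r)
        expected = suppression_oracle(
            [c.position for c in minima], [c.density for c in minima], 2.0 * r
        )
        got = detect_candidates_2r(tomo, DetectParams(radius_angstrom=r))
        assert [c.position for c in got] == expected

    def test_4r_minima_subset_of_2r_minima(self, rng):
        r = 3
        vol = rng.normal(size=(28, 28, 28))
        tomo = _tomo(vol, ps=1.0)
        wide = {c.position for c in find_local_minima(tomo, 4 * r)}
        narrow = {c.position for c in find_local_minima(tomo, 2 * r)}
        assert wide <= narrow

    def test_deterministic(self, rng):
        vol = rng.normal(size=(26, 26, 26))
        p = DetectParams(radius_angstrom=3)
        a = detect_candidates_2r(_tomo(vol, ps=1.0), p)
        b = detect_candidates_2r(_tomo(vol.copy(), ps=1.0), p)
        assert [(c.position, c.density) for c in a] == [(c.position, c.density) for c in b]


class TestExcludeMasked:
    def _cands(self, rng, n=30, size=20):
        from tomopick.particles import Candidate

        return [
            Candidate(position=tuple(int(v) for v in rng.integers(0, size, 3)), density=-1.0)
            for _ in range(n)
        ]

    def test_empty_mask_retains_all(self, rng):
        cands = self._cands(rng)
        out = exclude_masked(cands, np.zeros((20, 20, 20), dtype=bool))
        assert all(c.status == STATUS_CANDIDATE for c in out)

    def test_full_mask_rejects_all(self, rng):
        out = exclude_masked(self._cands(rng), np.ones((20, 20, 20), dtype=bool))
        assert all(c.status == STATUS_REJECTED_MASK for c in out)

    def test_half_volume_mask_matches_lookup_oracle(self, rng):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[:10] = True  # z < nz/2 masked
        cands = self._cands(rng)
        out = exclude_masked(cands, mask)
        for before, after in zip(cands, out):
            x, y, z = before.position
            expected = STATUS_REJECTED_MASK if mask[z, y, x] else STATUS_CANDIDATE
            assert after.status == expected
        assert [c.position for c in out] == [c.position for c in cands]  # order kept

    def test_growing_mask_never_increases_retained(self, rng):
        cands = self._cands(rng, n=50)
        small = rng.random((20, 20, 20)) < 0.2
        big = small | (rng.random((20, 20, 20)) < 0.2)
        kept_small = sum(c.status == STATUS_CANDIDATE for c in exclude_masked(cands, small))
        kept_big = sum(c.status == STATUS_CANDIDATE for c in exclude_masked(cands, big))
        assert kept_big <= kept_small

    def test_shape_mismatch_raises(self, rng):
        from tomopick.particles import Candidate

        with pytest.raises(ValueError):
            exclude_masked(
                [Candidate(position=(25, 0, 0), density=0.0)],
                np.zeros((10, 10, 10), dtype=bool),
            )


class TestRestrictSlab:
    def _at(self, zs):
        from tomopick.particles import Candidate

        return [Candidate(position=(5, 5, z), density=-1.0) for z in zs]

    def test_full_width_retains_everything(self):
        out = restrict_slab(self._at([0, 10, 31]), width_slices=64, nz=32)
        assert all(c.status == STATUS_CANDIDATE for c in out)

    def test_narrow_band_keeps_midplane_only(self):
        out = restrict_slab(self._at([0, 16]), width_slices=10, nz=32)
        assert out[0].status == STATUS_REJECTED_SLAB
        assert out[1].status == STATUS_CANDIDATE

    def test_boundary_inclusive(self):
        # |z - nz/2| <= width/2 keeps z = 16 +- 5 for width 10, nz 32
        out = restrict_slab(self._at([11, 21, 10, 22]), width_slices=10, nz=32)
        assert [c.status for c in out] == [
            STATUS_CANDIDATE, STATUS_CANDIDATE, STATUS_REJECTED_SLAB, STATUS_REJECTED_SLAB,
        ]


class TestRejectBoundary:
    def test_margin_enforced_for_subvolume(self):
        from tomopick.particles import Candidate

        r = 4
        margin = filter_subvolume_side(r) // 2
        inside = Candidate(position=(margin, margin, margin), density=0.0)
        outside = Candidate(position=(margin - 1, margin, margin), density=0.0)
        out = reject_boundary([inside, outside], (40, 40, 40), margin)
        assert out[0].status == STATUS_CANDIDATE
        assert out[1].status == "rejected_boundary"

    def test_subvolume_side_is_odd(self):
        assert filter_subvolume_side(4) == 13
        assert filter_subvolume_side(5) == 15
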