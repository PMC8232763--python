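import math

import numpy as np
import pytest

from c2fseg import (LabelVolume, MetricsReport, SurfacePointSet, asd,
                    dice_coefficient, evaluate_case, extract_surface, hausdorff,
                    summarize_reports)
from conftest import random_mask_pair


def brute_force_surface(mask):
    """Exhaustive 6-neighbour scan."""
    fg = mask.data > 0
    pts = []
    shape = fg.shape
    for z, y, x in np.argwhere(fg):
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]) \
                    or not fg[nz, ny, nx]:
                pts.append((z * mask.spacing[0], y * mask.spacing[1], x * mask.spacing[2]))
                break
    return np.array(pts)


def brute_force_directed(a_pts, b_pts):
    return np.array([min(math.dist(a, b) for b in b_pts) for a in a_pts])


def brute_force_asd(a_pts, b_pts):
    return (brute_force_directed(a_pts, b_pts).mean()
            + brute_force_directed(b_pts, a_pts).mean()) / 2


def brute_force_hd(a_pts, b_pts, percentile):
    def h(src, dst):
        d = sorted(brute_force_directed(src, dst))
        return d[max(1, math.ceil(percentile * len(d))) - 1]
    return max(h(a_pts, b_pts), h(b_pts, a_pts))


def cube_mask(shape, lo, hi, spacing=(1.0, 1.0, 1.0)):
    data = np.zeros(shape, dtype=np.uint8)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1
    return LabelVolume(data=data, spacing=spacing)


class TestDice:
    def test_identical(self):
        m = cube_mask((6, 6, 6), (1, 1, 1), (4, 4, 4))
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint(self):
        a = cube_mask((6, 6, 6), (0, 0, 0), (2, 2, 2))
        b = cube_mask((6, 6, 6), (4, 4, 4), (6, 6, 6))
        assert dice_coefficient(a, b) == 0.0

    def test_half_overlap(self):
        a = cube_mask((4, 4, 4), (0, 0, 0), (1, 1, 2))  # voxels (0,0,0),(0,0,1)
        b = cube_mask((4, 4, 4), (0, 0, 1), (1, 1, 3))  # voxels (0,0,1),(0,0,2)
        assert dice_coefficient(a, b) == pytest.approx(0.5)

    def test_geometry_mismatch(self):
        a = cube_mask((4, 4, 4), (0, 0, 0), (2, 2, 2))
        b = cube_mask((4, 4, 5), (0, 0, 0), (2, 2, 2))
        with pytest.raises(ValueError):
            dice_coefficient(a, b)


class TestSurface:
    def test_single_voxel(self):
        m = cube_mask((5, 5, 5), (2, 2, 2), (3, 3, 3), spacing=(0.5, 0.5, 0.5))
        surf = extract_surface(m)
        assert np.allclose(surf.points, [[1.0, 1.0, 1.0]])

    def test_solid_cube_shell(self):
        m = cube_mask((5, 5, 5), (1, 1, 1), (4, 4, 4))
        surf = extract_surface(m)
        assert len(surf) == 26  # 27 voxels minus the interior centre

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            a, _ = random_mask_pair(rng, shape=(10, 10, 10), spacing=(0.7, 1.1, 0.9))
            got = {tuple(p) for p in np.round(extract_surface(a).points, 9)}
            want = {tuple(p) for p in np.round(brute_force_surface(a), 9)}
            assert got == want

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_surface(LabelVolume(data=np.zeros((3, 3, 3), dtype=np.uint8)))


class TestDistances:
    def test_identical_sets_zero(self):
        s = SurfacePointSet(points=[[0, 0, 0], [1, 2, 3.0]])
        assert asd(s, s) == 0.0
        assert hausdorff(s, s, 0.95) == 0.0

    def test_single_pair_distance(self):
        # voxels 3 apart along x at 0.5 mm isotropic spacing -> 1.5 mm
        a = SurfacePointSet(points=[[0.0, 0.0, 0.0]])
        b = SurfacePointSet(points=[[0.0, 0.0, 1.5]])
        assert asd(a, b) == pytest.approx(1.5)

    def test_hausdorff_singleton_rank_rule(self):
        a = SurfacePointSet(points=[[0.0, 0.0, 0.0]])
        b = SurfacePointSet(points=[[0.0, 0.0, 4.0]])
        assert hausdorff(a, b, 0.95) == pytest.approx(4.0)

    def test_against_brute_force(self, rng):
        for _ in range(5):
            a, b = random_mask_pair(rng, shape=(12, 12, 12), spacing=(0.8, 1.0, 1.2))
            sa, sb = extract_surface(a), extract_surface(b)
            assert asd(sa, sb) == pytest.approx(
                brute_force_asd(sa.points, sb.points), abs=1e-9)
            for p in (1.0, 0.95, 0.5):
                assert hausdorff(sa, sb, p) == pytest.approx(
                    brute_force_hd(sa.points, sb.points, p), abs=1e-9)

    def test_invalid_percentile(self):
        s = SurfacePointSet(points=[[0, 0, 0.0]])
        with pytest.raises(ValueError):
            hausdorff(s, s, 0.0)


class TestEvaluateCase:
    def test_perfect(self):
        m = cube_mask((6, 6, 6), (1, 1, 1), (5, 5, 5))
        rep = evaluate_case(m, m)
        assert (rep.dice, rep.asd_mm, rep.hd95_mm, rep.hd_mm) == (1.0, 0.0, 0.0, 0.0)

    def test_shifted_cube_composite(self):
        a = cube_mask((8, 8, 8), (2, 2, 2), (5, 5, 5))
        b = cube_mask((8, 8, 8), (2, 2, 3), (5, 5, 6))
        rep = evaluate_case(a, b)
        sa, sb = extract_surface(a), extract_surface(b)
        assert rep.dice == pytest.approx(dice_coefficient(a, b))
        assert rep.asd_mm == pytest.approx(brute_force_asd(sa.points, sb.points), abs=1e-9)
        assert rep.hd95_mm == pytest.approx(brute_force_hd(sa.points, sb.points, 0.95), abs=1e-9)
        assert rep.hd_mm == pytest.approx(brute_force_hd(sa.points, sb.points, 1.0), abs=1e-9)

    def test_both_empty(self):
        z = LabelVolume(data=np.zeros((4, 4, 4), dtype=np.uint8))
        rep = evaluate_case(z, z)
        assert rep == MetricsReport(dice=1.0, asd_mm=0.0, hd95_mm=0.0, hd_mm=0.0)

    def test_one_empty_sentinel(self):
        z = LabelVolume(data=np.zeros((4, 4, 4), dtype=np.uint8))
        m = cube_mask((4, 4, 4), (1, 1, 1), (3, 3, 3))
        with pytest.warns(UserWarning, match="undefined"):
            rep = evaluate_case(z, m)
        assert rep.dice == 0.0
        assert np.isnan(rep.asd_mm) and np.isnan(rep.hd_mm)

    def test_rank_ordering_invariant(self, rng):
        for _ in range(50):
            a, b = random_mask_pair(rng, shape=(8, 8, 8))
            rep = evaluate_case(a, b)
            assert rep.hd95_mm <= rep.hd_mm + 1e-12
            assert rep.asd_mm <= rep.hd_mm + 1e-12


class TestInvariants:
    def test_symmetry(self, rng):
        a, b = random_mask_pair(rng, spacing=(0.5, 0.7, 0.9))
        r1, r2 = evaluate_case(a, b), evaluate_case(b, a)
        assert r1.asd_mm == pytest.approx(r2.asd_mm, abs=1e-12)
        assert r1.hd_mm == pytest.approx(r2.hd_mm, abs=1e-12)
        assert r1.hd95_mm == pytest.approx(r2.hd95_mm, abs=1e-12)
        assert r1.dice == pytest.approx(r2.dice)

    def test_spacing_scaling(self, rng):
        a, b = random_mask_pair(rng, spacing=(1.0, 1.0, 1.0))
        k = 2.5
        ak = LabelVolume(data=a.data, spacing=tuple(k * s for s in a.spacing))
        bk = LabelVolume(data=b.data, spacing=tuple(k * s for s in b.spacing))
        r1, rk = evaluate_case(a, b), evaluate_case(ak, bk)
        assert rk.dice == pytest.approx(r1.dice)
        assert rk.asd_mm == pytest.approx(k * r1.asd_mm, rel=1e-12)
        assert rk.hd_mm == pytest.approx(k * r1.hd_mm, rel=1e-12)
        assert rk.hd95_mm == pytest.approx(k * r1.hd95_mm, rel=1e-12)

    def test_summary_table_layout(self, rng):
        a, b = random_mask_pair(rng)
        table = summarize_reports({"c1": evaluate_case(a, b), "c2": evaluate_case(a, a)})
        assert list(table.columns) == ["dice", "asd_mm", "hd95_mm", "hd_mm"]
        assert "mean" in table.index and "std" in table.index
        assert table.loc["mean", "dice"] == pytest.approx(
            (dice_coefficient(a, b) + 1.0) / 2)
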