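"""Voxel-based inference: statistic maps, permutations, TFCE, ROC, p_U."""
import itertools

import numpy as np
import pytest

from voxdose.grids import BinaryMask, Grid, ScalarVolume
from voxdose.vbstats import (
    DoseStack,
    TfceParams,
    mann_whitney,
    mean_dose,
    pu_curve,
    roc_auc,
    significance_levels,
    subregions,
    tfce_significance,
    tfce_transform,
    tmax_test,
    voxel_statistic_map,
)


def _stack_from_matrix(X, labels, grid=None):
    X = np.asarray(X, dtype=float)
    n_vox = X.shape[1]
    if grid is None:
        grid = Grid((n_vox, 1, 1), (1.0, 1.0, 1.0))
    roi = BinaryMask(np.ones(grid.shape, dtype=bool), grid)
    return DoseStack(X, labels, roi)


def _pooled_t(x1, x0):
    n1, n0 = len(x1), len(x0)
    ss = np.var(x1, ddof=1) * (n1 - 1) + np.var(x0, ddof=1) * (n0 - 1)
    sp2 = ss / (n1 + n0 - 2)
    if sp2 <= 0:
        return 0.0
    return (np.mean(x1) - np.mean(x0)) / np.sqrt(sp2 * (1 / n1 + 1 / n0))


class TestStatisticMap:
    def test_pooled_t_hand_value(self):
        # cases {2,4} vs controls {1,1}: pooled s^2 = 1, t = 2 (brute oracle)
        stack = _stack_from_matrix([[2.0], [4.0], [1.0], [1.0]], [1, 1, 0, 0])
        t = voxel_statistic_map(stack).data.ravel()[0]
        assert t == pytest.approx(_pooled_t([2, 4], [1, 1]))
        assert t == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        stack = _stack_from_matrix([[1.0], [3.0], [1.0], [3.0]], [1, 1, 0, 0])
        assert voxel_statistic_map(stack).data.ravel()[0] == 0.0

    def test_label_swap_negates(self, rng):
        X = rng.random((8, 6)) * 10
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        a = voxel_statistic_map(_stack_from_matrix(X, labels)).data
        b = voxel_statistic_map(_stack_from_matrix(X, 1 - labels)).data
        assert np.allclose(a, -b)

    def test_zero_variance_flagged_as_zero(self):
        stack = _stack_from_matrix([[5.0], [5.0], [5.0], [5.0]], [1, 1, 0, 0])
        assert voxel_statistic_map(stack).data.ravel()[0] == 0.0


def _tmax_brute(X, labels):
    """Full enumeration oracle for the max-statistic permutation p-value."""
    X = np.asarray(X, float)
    n = len(labels)
    n1 = int(np.sum(labels))
    obs = max(_pooled_t(X[np.asarray(labels) == 1, j], X[np.asarray(labels) == 0, j])
              for j in range(X.shape[1]))
    null = []
    for combo in itertools.combinations(range(n), n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(combo)] = True
        null.append(max(_pooled_t(X[sel, j], X[~sel, j]) for j in range(X.shape[1])))
    return sum(t >= obs - 1e-12 for t in null) / len(null)


class TestTmax:
    @pytest.mark.parametrize("n1,n0,n_vox,seed", [(2, 2, 1, 0), (3, 3, 4, 1), (4, 5, 8, 2)])
    def test_exact_enumeration_matches_brute_force(self, n1, n0, n_vox, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((n1 + n0, n_vox)) * 50
        labels = np.array([1] * n1 + [0] * n0)
        res = tmax_test(_stack_from_matrix(X, labels), n_perm=10_000, seed=0)
        assert res.exact
        assert res.p_value == pytest.approx(_tmax_brute(X, labels))

    def test_p_value_lower_bound(self, rng):
        X = rng.random((12, 5))
        labels = np.array([1] * 4 + [0] * 8)
        res = tmax_test(_stack_from_matrix(X, labels), n_perm=200, seed=3)
        assert res.p_value >= 1.0 / (res.n_permutations + 1)

    def test_group_required(self, rng):
        with pytest.raises(ValueError):
            _stack_from_matrix(rng.random((4, 2)), [1, 1, 1, 1])


def _naive_tfce_steps(stat, roi, E, H, n_steps, conn, ext_mul):
    """Independent stepped oracle (per-threshold labeling, exact truncation)."""
    from scipy import ndimage

    struct = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[conn])
    t = np.where(roi, np.maximum(stat, 0.0), 0.0)
    tmax = t.max()
    out = np.zeros_like(t)
    if tmax <= 0:
        return out
    edges = np.linspace(0, tmax, n_steps + 1)
    for k in range(n_steps):
        a, b = edges[k], edges[k + 1]
        m = 0.5 * (a + b)
        lab_m, _ = ndimage.label((t >= m) & roi, struct)
        sz_m = np.bincount(lab_m.ravel())
        lab_a, _ = ndimage.label((t > a) & roi, struct)
        sz_a = np.bincount(lab_a.ravel())
        act = (t > a) & roi
        e = np.where(t >= m, sz_m[lab_m], sz_a[lab_a]) * ext_mul
        w = (np.minimum(t, b) ** (H + 1) - a ** (H + 1)) / (H + 1)
        out[act] += e[act] ** E * w[act]
    return out


class TestTfceTransform:
    def test_isolated_voxel_analytic(self):
        grid = Grid((3, 3, 3), (1.0, 1.0, 1.0))
        stat = np.zeros(grid.shape)
        stat[1, 1, 1] = 2.0
        out = tfce_transform(
            ScalarVolume(stat, grid),
            BinaryMask(np.ones(grid.shape, bool), grid),
            TfceParams(extent_measure="voxels"),
        )
        # integral of h^2 from 0 to 2 = 8/3
        assert out.data[1, 1, 1] == pytest.approx(8 / 3, rel=1e-6)

    def test_constant_component_analytic(self):
        grid = Grid((2, 2, 4), (1.0, 1.0, 1.0))
        stat = np.zeros(grid.shape)
        stat[:, :, :2] = 1.0  # one 8-voxel component at height 1
        out = tfce_transform(
            ScalarVolume(stat, grid),
            BinaryMask(np.ones(grid.shape, bool), grid),
            TfceParams(extent_measure="voxels"),
        )
        assert out.data[0, 0, 0] == pytest.approx(np.sqrt(8) / 3, rel=1e-6)

    def test_all_zero_map(self, unit_grid):
        out = tfce_transform(
            ScalarVolume(np.zeros(unit_grid.shape), unit_grid),
            BinaryMask(np.ones(unit_grid.shape, bool), unit_grid),
        )
        assert np.all(out.data == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_matches_stepped_oracle(self, seed, unit_grid):
        rng = np.random.default_rng(seed)
        stat = ScalarVolume(rng.normal(0.3, 1.0, unit_grid.shape), unit_grid)
        roi = BinaryMask(rng.random(unit_grid.shape) < 0.8, unit_grid)
        exact = tfce_transform(stat, roi, TfceParams()).data
        oracle = _naive_tfce_steps(
            stat.data, roi.data, 0.5, 2.0, 2000, 26, unit_grid.voxel_volume
        )
        floor = 1e-3 * oracle.max()
        assert np.abs(exact - oracle).max() <= 0.01 * max(oracle.max(), 1e-12)
        rel = np.abs(exact - oracle) / np.maximum(oracle, floor)
        assert rel.max() <= 0.01

    def test_monotone_in_single_voxel_raise(self):
        grid = Grid((5, 5, 5), (1.0, 1.0, 1.0))
        rng = np.random.default_rng(9)
        roi = BinaryMask(np.ones(grid.shape, bool), grid)
        base = np.abs(rng.normal(0.5, 0.5, grid.shape))
        out0 = tfce_transform(ScalarVolume(base, grid), roi).data
        for _ in range(5):
            idx = tuple(rng.integers(0, 5, 3))
            bumped = base.copy()
            bumped[idx] += rng.uniform(0.1, 1.0)
            out1 = tfce_transform(ScalarVolume(bumped, grid), roi).data
            assert np.all(out1 >= out0 - 1e-12)


class TestSignificanceAndSubregions:
    def test_p_lower_bound_and_recovery_direction(self):
        rng = np.random.default_rng(5)
        grid = Grid((6, 6, 6), (2.0, 2.0, 2.0))
        roi = BinaryMask(np.ones(grid.shape, bool), grid)
        X = rng.normal(50, 2, (14, roi.n_voxels))
        labels = np.array([1] * 5 + [0] * 9)
        # plant a strong localized effect in a corner block of the ROI
        planted = np.zeros(grid.shape, bool)
        planted[:3, :3, :3] = True
        cols = planted.ravel()[roi.data.ravel()]
        X[np.ix_(labels == 1, cols)] += 15.0
        stack = DoseStack(X, labels, roi)
        sig = tfce_significance(stack, TfceParams(), n_perm=300, seed=2)
        p_roi = sig.p.data[roi.data]
        assert p_roi.min() >= 1.0 / (sig.n_permutations + 1) - 1e-12
        assert np.all(p_roi > 0) and np.all(p_roi <= 1)
        # the most significant voxel lies inside the planted block
        best = np.unravel_index(np.argmin(sig.p.data + ~roi.data), grid.shape)
        assert planted[best]

    def test_subregion_nesting_and_limits(self):
        rng = np.random.default_rng(6)
        grid = Grid((5, 5, 5), (1.0, 1.0, 1.0))
        roi = BinaryMask(rng.random(grid.shape) < 0.7, grid)
        p = np.ones(grid.shape)
        p[roi.data] = rng.uniform(0.01, 1.0, roi.n_voxels)
        from voxdose.vbstats import SignificanceMap

        sig = SignificanceMap(ScalarVolume(p, grid), roi, 1000, 0, False)
        fam = subregions(sig, [0.001, 0.05, 0.5, 1.0])
        assert fam.masks[0].n_voxels == 0  # below the minimum p
        assert np.array_equal(fam.masks[-1].data, roi.data)  # p=1 gives the ROI
        for a, b in zip(fam.masks[:-1], fam.masks[1:]):
            assert not (a.data & ~b.data).any()
        assert 0.05 in significance_levels()

    def test_invalid_levels_rejected(self):
        grid = Grid((3, 3, 3), (1.0, 1.0, 1.0))
        roi = BinaryMask(np.ones(grid.shape, bool), grid)
        from voxdose.vbstats import SignificanceMap

        sig = SignificanceMap(ScalarVolume(np.ones(grid.shape), grid), roi, 10, 0, False)
        with pytest.raises(ValueError):
            subregions(sig, [0.0, 0.5])


class TestMeanDose:
    def test_uniform_and_two_voxel(self):
        grid = Grid((3, 3, 3), (1.0, 1.0, 1.0))
        dose = np.full(grid.shape, 70.0)
        region = np.zeros(grid.shape, bool)
        region[0, 0, 0] = True
        assert mean_dose(ScalarVolume(dose, grid), BinaryMask(region, grid)) == 70.0
        dose[0, 0, 0], dose[0, 0, 1] = 10.0, 20.0
        region[0, 0, 1] = True
        assert mean_dose(ScalarVolume(dose, grid), BinaryMask(region, grid)) == 15.0

    def test_empty_region_rejected(self, unit_grid):
        with pytest.raises(ValueError):
            mean_dose(
                ScalarVolume(np.ones(unit_grid.shape), unit_grid),
                BinaryMask(np.zeros(unit_grid.shape, bool), unit_grid),
            )


class TestRocAuc:
    def test_perfect_and_chance(self):
        assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([2, 3, 1, 4], [1, 1, 0, 0]) == 0.5

    def test_flip_symmetry(self, rng):
        vals = rng.random(20)
        labels = (rng.random(20) < 0.4).astype(int)
        if labels.sum() in (0, 20):
            labels[:3] = [0, 1, 1]
        assert roc_auc(vals, labels) + roc_auc(vals, 1 - labels) == pytest.approx(1.0)

    def test_equals_normalized_mann_whitney_u(self, rng):
        vals = np.round(rng.random(18) * 5) / 5  # force ties
        labels = np.array([1] * 6 + [0] * 12)
        u, _ = mann_whitney(vals[labels == 1], vals[labels == 0])
        assert roc_auc(vals, labels) == pytest.approx(u / (6 * 12))

    def test_bootstrap_ci_brackets_auc(self, rng):
        vals = np.concatenate([rng.normal(1, 1, 10), rng.normal(0, 1, 20)])
        labels = np.array([1] * 10 + [0] * 20)
        auc, (lo, hi) = roc_auc(vals, labels, ci=(500, 0))
        assert lo <= auc <= hi

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


def _mw_brute(x, y, alternative):
    """Enumeration oracle over all label assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(sel):
        xs, ys = pooled[sel], pooled[~sel]
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    obs_sel = np.zeros(len(pooled), bool)
    obs_sel[:n1] = True
    u_obs = u_of(obs_sel)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), bool)
        sel[list(combo)] = True
        us.append(u_of(sel))
    us = np.asarray(us)
    p_g = np.mean(us >= u_obs - 1e-12)
    p_l = np.mean(us <= u_obs + 1e-12)
    if alternative == "greater":
        return p_g
    if alternative == "less":
        return p_l
    return min(1.0, 2 * min(p_g, p_l))


class TestMannWhitney:
    def test_hand_example(self):
        _, p = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_degenerate(self):
        _, p = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.5, 1, 4)
        y = rng.normal(0, 1, 5)
        for alt in ("two-sided", "greater"):
            _, p = mann_whitney(x, y, alt)
            assert p == pytest.approx(_mw_brute(x, y, alt))

    def test_exact_close_to_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.8, 1, 6)
        y = rng.normal(0, 1, 6)
        _, p_exact = mann_whitney(x, y)
        from scipy.stats import mannwhitneyu

        p_approx = mannwhitneyu(x, y, method="asymptotic").pvalue
        assert abs(p_exact - p_approx) < 0.02


class TestPuCurve:
    def _family(self, grid, roi, levels_masks):
        from voxdose.vbstats import SubregionFamily

        levels = np.array(sorted(levels_masks))
        masks = [BinaryMask(levels_masks[l], grid, f"S_{l}") for l in levels]
        vols = np.array([m.volume_cm3 for m in masks])
        return SubregionFamily(levels, masks, vols)

    def test_identical_doses_give_flat_curve(self):
        grid = Grid((4, 4, 4), (1.0, 1.0, 1.0))
        roi = BinaryMask(np.ones(grid.shape, bool), grid)
        X = np.full((6, roi.n_voxels), 50.0)
        stack = DoseStack(X, [1, 1, 1, 0, 0, 0], roi)
        m = np.zeros(grid.shape, bool)
        m[:2] = True
        fam = self._family(grid, roi, {0.05: m, 1.0: roi.data})
        out = pu_curve(fam, stack)
        assert np.all(out["p_u"][np.isfinite(out["p_u"])] == 1.0)

    def test_empty_members_skipped_and_levels_sorted(self, rng):
        grid = Grid((4, 4, 4), (1.0, 1.0, 1.0))
        roi = BinaryMask(np.ones(grid.shape, bool), grid)
        X = rng.normal(40, 5, (8, roi.n_voxels))
        stack = DoseStack(X, [1, 1, 1, 0, 0, 0, 0, 0], roi)
        empty = np.zeros(grid.shape, bool)
        m = np.zeros(grid.shape, bool)
        m[0, 0, :] = True
        fam = self._family(grid, roi, {0.01: empty, 0.05: m, 1.0: roi.data})
        out = pu_curve(fam, stack)
        assert np.isnan(out["p_u"][0])
        assert np.all(np.diff(out["levels"]) > 0)
        assert np.isfinite(out["min_p_u"])

    def test_all_empty_rejected(self, rng):
        grid = Grid((4, 4, 4), (1.0, 1.0, 1.0))
        roi = BinaryMask(np.ones(grid.shape, bool), grid)
        X = rng.normal(40, 5, (6, roi.n_voxels))
        stack = DoseStack(X, [1, 1, 1, 0, 0, 0], roi)
        empty = np.zeros(grid.shape, bool)
        fam = self._family(grid, roi, {0.01: empty})
        with pytest.raises(ValueError):
            pu_curve(fam, stack)
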