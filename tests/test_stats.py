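"""Statistical core: residualization and enumeration oracles, cluster
flood-fill oracle, ROI geometry, Meng's test and per-cycle analyses."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swalink.errors import AlignmentError, ConfigurationError, DegenerateInputError
from swalink.inverse import CurrentDensityMap
from swalink.simulate import CohortConfig, simulate_current_density_cohort
from swalink.stats import (
    build_roi_sphere,
    critical_r,
    extract_clusters,
    meng_dependent_correlation_test,
    mirror_roi,
    partial_correlation,
    per_cycle_analysis,
    permutation_fwer_threshold,
    roi_mean_density,
    voxelwise_partial_correlation,
)


def oracle_partial_r(x, y, z):
    """Independent two-stage oracle: OLS-residualize, then np.corrcoef."""
    Z = np.column_stack([np.ones(len(x)), np.atleast_2d(z).T])
    rx = x - Z @ np.linalg.solve(Z.T @ Z, Z.T @ x)
    ry = y - Z @ np.linalg.solve(Z.T @ Z, Z.T @ y)
    return np.corrcoef(rx, ry)[0, 1]


class TestPartialCorrelation:
    def test_intercept_only_equals_plain_pearson(self, rng):
        x, y = rng.standard_normal((2, 30))
        r, _, df = partial_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        assert df == 28

    def test_matches_residualize_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        z = np.array([1.0, 1, 2, 2, 3])
        r, _, df = partial_correlation(x, y, covariates=z)
        assert r == pytest.approx(oracle_partial_r(x, y, z), abs=1e-12)
        assert df == 2

    def test_random_instances_match_oracle(self, rng):
        for _ in range(10):
            x, y = rng.standard_normal((2, 20))
            z = rng.standard_normal((20, 2))
            r, _, _ = partial_correlation(x, y, covariates=z)
            Z = np.column_stack([np.ones(20), z])
            rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
            ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
            assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_critical_r_at_n52(self):
        """Two-sided p = 0.05 at n = 52 (df = 50) is attained at |r| = 0.273."""
        assert critical_r(52, 0.05) == pytest.approx(0.273, abs=5e-4)
        r, p, _ = partial_correlation(*_vectors_with_r(52, 0.2732))
        assert p == pytest.approx(0.05, abs=2e-3)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            partial_correlation(np.ones(10), np.arange(10.0))


def _vectors_with_r(n, r, seed=0):
    """Construct x, y with an exact sample correlation r."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    w = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    w = w - w.mean()
    w -= x * (w @ x) / (x @ x)
    w /= np.linalg.norm(w)
    y = r * x / np.linalg.norm(x) + np.sqrt(1 - r**2) * w
    return x, y


class TestVoxelwise:
    def test_behavior_equal_to_voxel_gives_r_one(self, rng):
        maps = rng.standard_normal((10, 5))
        sm = voxelwise_partial_correlation(maps, maps[:, 2])
        assert sm.r[2] == pytest.approx(1.0)

    def test_matches_per_voxel_loop(self, rng):
        maps = rng.standard_normal((10, 20))
        y = rng.standard_normal(10)
        z = rng.standard_normal(10)
        sm = voxelwise_partial_correlation(maps, y, covariates=z)
        for v in range(20):
            r, p, _ = partial_correlation(maps[:, v], y, covariates=z)
            assert sm.r[v] == pytest.approx(r, abs=1e-12)
            assert sm.p[v] == pytest.approx(p, abs=1e-12)

    def test_subject_order_invariance(self, rng):
        maps = rng.standard_normal((12, 6))
        y = rng.standard_normal(12)
        perm = rng.permutation(12)
        a = voxelwise_partial_correlation(maps, y)
        b = voxelwise_partial_correlation(maps[perm], y[perm])
        np.testing.assert_allclose(a.r, b.r, atol=1e-12)

    def test_constant_voxel_excluded_and_reported(self, rng):
        maps = rng.standard_normal((10, 4))
        maps[:, 1] = 7.0
        sm = voxelwise_partial_correlation(maps, rng.standard_normal(10))
        assert list(sm.excluded_voxels) == [1]
        assert np.isnan(sm.r[1])


class TestPermutation:
    def test_exhaustive_enumeration_oracle(self, rng):
        """Feeding all 120 permutations of n = 5 reproduces the
        independently enumerated null distribution of the max |r|."""
        n, V = 5, 3
        maps = rng.standard_normal((n, V))
        y = rng.standard_normal(n)
        z = rng.standard_normal(n)
        perms = np.array(list(itertools.permutations(range(n))))
        res = permutation_fwer_threshold(maps, y, covariates=z,
                                         permutations=perms, alpha=0.05)
        # oracle: per permutation, loop voxels with the two-stage formula
        Z = np.column_stack([np.ones(n), z])
        e = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        oracle = []
        for p in perms:
            vals = [abs(oracle_partial_r(maps[:, v], e[list(p)], z))
                    for v in range(V)]
            oracle.append(max(vals))
        np.testing.assert_allclose(np.sort(res.null_max), np.sort(oracle),
                                   atol=1e-12)

    def test_alpha_monotonicity(self, rng):
        cd = simulate_current_density_cohort(CohortConfig(seed=5, r_true=-0.7))
        logm = np.log10(np.maximum(cd.maps, 1e-12))
        masks = []
        for alpha in (0.01, 0.05, 0.10):
            res = permutation_fwer_threshold(logm, cd.behavior, cd.tst,
                                             n_perm=300, alpha=alpha, seed=1)
            masks.append(res.significant)
        assert np.all(masks[0] <= masks[1]) and np.all(masks[1] <= masks[2])

    def test_constant_behavior_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            permutation_fwer_threshold(rng.standard_normal((8, 3)),
                                       np.ones(8), n_perm=10)

    def test_small_n_warns_about_factorial(self, rng):
        maps = rng.standard_normal((4, 2))
        y = rng.standard_normal(4)
        with pytest.warns(UserWarning, match="distinct permutations"):
            permutation_fwer_threshold(maps, y, n_perm=100, seed=0)

    def test_planted_effect_recovered_across_seeds(self):
        """r_true = −0.6 at n = 52: the effect voxel is whole-brain
        significant in at least 80% of 50 seeded cohorts."""
        hits = 0
        for seed in range(50):
            cd = simulate_current_density_cohort(
                CohortConfig(seed=seed, r_true=-0.6))
            logm = np.log10(np.maximum(cd.maps, 1e-12))
            res = permutation_fwer_threshold(logm, cd.behavior, cd.tst,
                                             n_perm=1000, alpha=0.05, seed=seed)
            hits += int(res.significant[cd.effect_voxel])
        assert hits >= 40

    def test_roi_correlation_tracks_realized_effect(self):
        """ROI-level r̂ lies within ±0.15 of the generator's realized
        effect-voxel correlation."""
        diffs = []
        for seed in range(10):
            cd = simulate_current_density_cohort(
                CohortConfig(seed=seed, r_true=-0.6))
            logm = np.log10(np.maximum(cd.maps, 1e-12))
            realized = np.corrcoef(cd.bundle.effect_field, cd.behavior)[0, 1]
            r, _, _ = partial_correlation(logm[:, cd.effect_voxel], cd.behavior,
                                          covariates=cd.tst)
            diffs.append(abs(r - realized))
        assert max(diffs) <= 0.15


def flood_fill_components(mask, ijk, connectivity=26):
    """Independent oracle: BFS flood fill over the masked lattice."""
    on = {tuple(c) for c, m in zip(ijk, mask) if m}
    comps = []
    while on:
        seed = on.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            c = frontier.pop()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        if (dx, dy, dz) == (0, 0, 0):
                            continue
                        if connectivity == 6 and abs(dx) + abs(dy) + abs(dz) != 1:
                            continue
                        nb = (c[0] + dx, c[1] + dy, c[2] + dz)
                        if nb in on:
                            on.remove(nb)
                            comp.add(nb)
                            frontier.append(nb)
        comps.append(comp)
    return comps


class TestClusters:
    def grid(self, n=6):
        from swalink.headmodel import voxel_lattice

        return voxel_lattice(n, 5.0)

    def test_four_adjacent_voxels_500_mm3(self):
        grid = self.grid()
        mask = np.zeros(len(grid), bool)
        target = [(2.5, 2.5, 2.5), (7.5, 2.5, 2.5), (2.5, 7.5, 2.5),
                  (2.5, 2.5, 7.5)]
        for tcoord in target:
            mask[np.flatnonzero((grid == tcoord).all(axis=1))[0]] = True
        cs = extract_clusters(mask, grid)
        assert len(cs) == 1
        assert cs.clusters[0].size_mm3 == pytest.approx(500.0)

    def test_separated_voxels_form_two_clusters(self):
        grid = self.grid()
        mask = np.zeros(len(grid), bool)
        mask[0] = True
        far = np.argmax(np.linalg.norm(grid - grid[0], axis=1))
        mask[far] = True
        assert len(extract_clusters(mask, grid)) == 2

    def test_random_masks_match_flood_fill(self, rng):
        grid = self.grid(5)
        ijk = np.round((grid - grid.min(0)) / 5.0).astype(int)
        for conn in (26, 6):
            for _ in range(10):
                mask = rng.random(len(grid)) < 0.25
                cs = extract_clusters(mask, grid, connectivity=conn)
                oracle = flood_fill_components(mask, ijk, conn)
                assert len(cs) == len(oracle)
                sizes = sorted(len(c.voxel_indices) for c in cs)
                assert sizes == sorted(len(c) for c in oracle)

    def test_peak_is_max_abs_r_lowest_index_on_ties(self):
        grid = self.grid(3)
        mask = np.ones(len(grid), bool)
        r = np.zeros(len(grid))
        r[4] = -0.9
        r[10] = 0.9
        cs = extract_clusters(mask, grid, r=r)
        assert cs.clusters[0].peak_index == 4

    def test_empty_mask_empty_set(self):
        grid = self.grid(3)
        assert len(extract_clusters(np.zeros(len(grid), bool), grid)) == 0


class TestROI:
    def test_radius_zero_is_center_voxel(self):
        from swalink.headmodel import voxel_lattice

        grid = voxel_lattice(5, 5.0)
        roi = build_roi_sphere(grid[12], grid, radius_mm=0.0)
        assert list(roi.voxel_indices) == [12]

    def test_15mm_sphere_has_123_lattice_voxels(self):
        """Lattice-point count for i²+j²+k² <= 9 is 123."""
        from swalink.headmodel import voxel_lattice

        grid = voxel_lattice(9, 5.0)
        center = grid[np.argmin(np.linalg.norm(grid, axis=1))]
        roi = build_roi_sphere(center, grid, radius_mm=15.0)
        assert roi.voxel_indices.size == 123
        # independent enumeration oracle
        count = sum(1 for i in range(-3, 4) for j in range(-3, 4)
                    for k in range(-3, 4) if i*i + j*j + k*k <= 9)
        assert count == 123

    def test_mirror_is_involution_with_equal_cardinality(self):
        from swalink.headmodel import voxel_lattice

        grid = voxel_lattice(6, 5.0)
        roi = build_roi_sphere(np.array([-7.5, 2.5, 2.5]), grid, radius_mm=12.0)
        m = mirror_roi(roi, grid)
        assert m.voxel_indices.size == roi.voxel_indices.size
        back = mirror_roi(m, grid)
        np.testing.assert_array_equal(np.sort(back.voxel_indices),
                                      np.sort(roi.voxel_indices))
        np.testing.assert_allclose(back.center, roi.center)

    def test_mirror_flips_x_coordinate(self):
        from swalink.headmodel import voxel_lattice

        grid = voxel_lattice(6, 5.0)
        roi = build_roi_sphere(np.array([-12.5, -7.5, 7.5]), grid, radius_mm=6.0)
        m = mirror_roi(roi, grid)
        np.testing.assert_allclose(m.center, [12.5, -7.5, 7.5])

    def test_roi_mean_density_hand_example(self):
        grid = np.zeros((4, 3))
        m = CurrentDensityMap(values=np.array([-1.0, -0.5, -0.5, -2.0]),
                              grid=grid, normalized=True, log_transformed=True)
        roi = build_roi_sphere(np.zeros(3), grid, radius_mm=1.0)
        assert roi_mean_density(m, roi) == pytest.approx(-1.0)

    def test_empty_roi_rejected(self):
        from swalink.headmodel import voxel_lattice

        grid = voxel_lattice(3, 5.0)
        with pytest.raises(AlignmentError):
            build_roi_sphere(np.array([500.0, 0, 0]), grid, radius_mm=1.0)


class TestMeng:
    def test_equal_correlations_give_z_zero(self):
        res = meng_dependent_correlation_test(0.4, 0.4, 0.3, 52)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p_one_sided == pytest.approx(0.5, abs=1e-12)

    def test_one_sided_tail_at_z_116(self):
        """One-sided normal p at Z = 1.16 rounds to 0.12."""
        from scipy import stats

        assert round(float(stats.norm.sf(1.16)), 2) == 0.12

    def test_hand_evaluated_example(self):
        """(r1=−0.45, r2=−0.20, r12=0.50, n=52) → Z ≈ −1.883 by stepwise
        evaluation of the formula chain."""
        res = meng_dependent_correlation_test(-0.45, -0.20, 0.50, 52)
        assert res.z == pytest.approx(-1.883, abs=1e-3)
        assert res.p_two_sided == pytest.approx(2 * (1 - res.p_one_sided), abs=1e-12)

    @given(r=st.floats(-0.9, 0.9), r12=st.floats(-0.5, 0.9))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_in_swapped_correlations(self, r, r12):
        a = meng_dependent_correlation_test(r, -r, r12, 40)
        b = meng_dependent_correlation_test(-r, r, r12, 40)
        assert a.z == pytest.approx(-b.z, abs=1e-10)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(DegenerateInputError):
            meng_dependent_correlation_test(1.0, 0.3, 0.2, 20)
        with pytest.raises(ConfigurationError):
            meng_dependent_correlation_test(0.5, 0.3, 0.2, 3)


class TestPerCycle:
    def _maps(self, rng, n_subj=10, n_cycles=4, n_vox=8):
        grid = np.arange(n_vox * 3, dtype=float).reshape(n_vox, 3)
        subj_maps, durations = [], []
        base = rng.uniform(1, 2, (n_subj, n_vox))
        for i in range(n_subj):
            subj_maps.append([CurrentDensityMap(values=base[i].copy(), grid=grid)
                              for _ in range(n_cycles)])
            durations.append([90.0 + 5 * c for c in range(n_cycles)])
        roi = build_roi_sphere(grid[0], grid, radius_mm=1e6)
        return subj_maps, durations, grid, roi

    def test_identical_cycles_identical_r(self, rng):
        subj_maps, durations, grid, roi = self._maps(rng)
        behavior = rng.standard_normal(10)
        # same duration for every cycle so the covariate matches too
        durations = [[100.0] * 4 for _ in range(10)]
        recs = per_cycle_analysis(subj_maps, behavior, durations, roi)
        rs = {rec.r for rec in recs if rec.cycle in "1234"}
        assert len(recs) == 5
        assert max(rs) - min(rs) < 1e-12

    def test_missing_cycles_excluded_listwise(self, rng):
        subj_maps, durations, grid, roi = self._maps(rng)
        subj_maps[0] = subj_maps[0][:2]     # subject 0 lacks cycles 3-4
        durations[0] = durations[0][:2]
        behavior = rng.standard_normal(10)
        recs = {r.cycle: r for r in per_cycle_analysis(subj_maps, behavior,
                                                       durations, roi)}
        assert recs["1"].n == 10 and recs["3"].n == 9
        assert recs["2-4"].n == 9

    def test_restricted_to_first_four_cycles(self, rng):
        subj_maps, durations, grid, roi = self._maps(rng, n_cycles=6)
        behavior = rng.standard_normal(10)
        recs = per_cycle_analysis(subj_maps, behavior, durations, roi)
        assert {r.cycle for r in recs} == {"1", "2", "3", "4", "2-4"}

    def test_planted_effect_consistent_across_cycles(self):
        """A planted effect constant across cycles yields negative r in
        every cycle for most seeds (r_true = −0.6, n = 52)."""
        neg = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cd = simulate_current_density_cohort(
                CohortConfig(seed=seed, r_true=-0.6))
            grid = cd.grid
            roi = build_roi_sphere(grid[cd.effect_voxel], grid, radius_mm=5.0)
            subj_maps = [[CurrentDensityMap(values=cd.maps[i], grid=grid)] * 4
                         for i in range(52)]
            durations = [[100.0, 95.0, 90.0, 85.0]] * 52
            recs = per_cycle_analysis(subj_maps, cd.behavior, durations, roi)
            neg += all(r.r < 0 for r in recs if r.cycle in "1234")
        assert neg >= int(0.9 * n_seeds)
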