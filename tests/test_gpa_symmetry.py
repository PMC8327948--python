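import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import morphomod as mm
from morphomod.gpa_symmetry import GPAError


def unit_square():
    return np.array(
        [[0.5, 0.5, 0.0], [-0.5, 0.5, 0.0], [-0.5, -0.5, 0.0], [0.5, -0.5, 0.0]]
    )


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        assert mm.centroid_size(unit_square()) == pytest.approx(np.sqrt(2.0))

    def test_scales_linearly(self):
        assert mm.centroid_size(3.0 * unit_square()) == pytest.approx(3.0 * np.sqrt(2.0))

    def test_rigid_motion_invariance(self, rng):
        config = rng.normal(size=(10, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        moved = config @ rot.T + np.array([5.0, -2.0, 1.0])
        assert mm.centroid_size(moved) == pytest.approx(mm.centroid_size(config))

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(GPAError, match="degenerate"):
            mm.centroid_size(np.ones((4, 3)))


def brute_force_procrustes_distance(a, b):
    """Independent oracle: minimise over rotations parameterised by Euler
    angles with a coarse grid followed by local refinement."""
    a = (a - a.mean(axis=0)) / mm.centroid_size(a)
    b = (b - b.mean(axis=0)) / mm.centroid_size(b)

    def dist(angles):
        rot = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.sum((a @ rot.T - b) ** 2))

    grid = np.linspace(-np.pi, np.pi, 13)
    best, best_angles = np.inf, None
    for az in grid:
        for ay in np.linspace(-np.pi / 2, np.pi / 2, 7):
            for ax in grid:
                d = dist((az, ay, ax))
                if d < best:
                    best, best_angles = d, (az, ay, ax)
    res = minimize(dist, best_angles, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
    return min(best, res.fun)


class TestGPA:
    def test_identical_under_rigid_motion_and_scaling(self, rng):
        base = rng.normal(size=(8, 3))
        configs = []
        for i in range(5):
            rot = Rotation.random(random_state=i).as_matrix()
            configs.append(2.0 ** (i - 2) * base @ rot.T + rng.normal(size=3) * 10)
        fit = mm.gpa(np.stack(configs))
        for cfg in fit.aligned:
            assert np.allclose(cfg, fit.aligned[0], atol=1e-8)

    def test_two_triangles_match_brute_force(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        oracle = brute_force_procrustes_distance(a, b)
        assert mm.procrustes_distance(a, b) == pytest.approx(oracle, abs=1e-4)

    def test_consensus_fixed_point(self, rng):
        fit = mm.gpa(rng.normal(size=(6, 7, 3)))
        refit = mm.gpa(fit.aligned)
        d = mm.procrustes_distance(refit.consensus, fit.consensus)
        assert d < 1e-8

    def test_output_invariant_to_input_rigid_motion(self, rng):
        coords = rng.normal(size=(5, 6, 3))
        fit1 = mm.gpa(coords)
        rot = Rotation.random(random_state=9).as_matrix()
        fit2 = mm.gpa(3.0 * coords @ rot.T + 1.0)
        for s1, s2 in zip(fit1.aligned, fit2.aligned):
            assert mm.procrustes_distance(s1, s2) < 1e-8
        np.testing.assert_allclose(fit2.centroid_size, 3.0 * fit1.centroid_size)

    def test_mirrored_specimen_raises_not_silently_reflected(self):
        # a left/right-inconsistent (mirrored) specimen is a data error
        cfg = np.random.default_rng(0).normal(size=(6, 3))
        mirrored = cfg * np.array([1.0, -1.0, 1.0])
        with pytest.raises(GPAError, match="reflection"):
            mm.gpa(np.stack([cfg, cfg, mirrored]))


class TestSymmetricComponent:
    def _pairing(self):
        return mm.SymmetryPairing(pairs=[(0, 1), (2, 3)], midline=[4, 5])

    def _symmetric_config(self, rng):
        cfg = np.zeros((6, 3))
        cfg[0] = rng.uniform(0.2, 1.0, 3)
        cfg[1] = cfg[0] * [1, -1, 1]
        cfg[2] = rng.uniform(-1.0, -0.2, 3) * [1, -1, 1]
        cfg[3] = cfg[2] * [1, -1, 1]
        cfg[4] = [0.5, 0.0, 0.8]
        cfg[5] = [-0.5, 0.0, -0.8]
        return cfg

    def test_symmetric_input_is_fixed_point(self, rng):
        cfgs = np.stack([self._symmetric_config(rng) for _ in range(4)])
        fit = mm.gpa(cfgs)
        sym, asym = mm.symmetric_component(fit, self._pairing())
        assert np.abs(asym).max() < 1e-8
        for orig, s in zip(fit.aligned, sym.aligned):
            assert mm.procrustes_distance(orig, s) < 1e-8
        assert sym.symmetric

    def test_mirror_pair_receives_same_symmetric_component(self, rng):
        cfg = self._symmetric_config(rng) + 0.05 * rng.normal(size=(6, 3))
        mirrored = mm.mirror_relabel(cfg, self._pairing())
        fit = mm.gpa(np.stack([cfg, mirrored, cfg, mirrored]))
        sym, _ = mm.symmetric_component(fit, self._pairing())
        assert mm.procrustes_distance(sym.aligned[0], sym.aligned[1]) < 1e-6

    def test_antisymmetric_perturbation_recovered_to_second_order(self, rng):
        base = self._symmetric_config(rng)
        eps = 1e-3
        delta = eps * np.array([0.3, 0.5, -0.2])
        perturbed = base.copy()
        # purely antisymmetric: opposite mirrored displacements on a pair
        perturbed[0] += delta
        perturbed[1] -= delta * np.array([1.0, -1.0, 1.0])
        others = [self._symmetric_config(rng) for _ in range(3)]
        fit = mm.gpa(np.stack([perturbed] + others))
        sym, _ = mm.symmetric_component(fit, self._pairing())
        base_unit = (base - base.mean(axis=0)) / mm.centroid_size(base)
        d = mm.procrustes_distance(sym.aligned[0], base_unit)
        assert d < 50 * eps**2

    def test_sym_plus_asym_reconstructs_joint_alignment(self, small_sim):
        sym, asym = small_sim["sym"], small_sim["asym"]
        recon = sym.aligned + asym
        # reconstruction equals the originals as aligned in the joint fit
        fit = small_sim["fit"]
        for orig, rec in zip(fit.aligned, recon):
            assert mm.procrustes_distance(orig, rec) < 1e-8


class TestSubsetModule:
    def test_subset_is_column_selection_of_joint_fit(self, small_sim):
        sym, mmap = small_sim["sym"], small_sim["module_map"]
        nc = mm.subset_module(sym, mmap, "NC")
        np.testing.assert_array_equal(nc.aligned, sym.aligned[:, mmap.indices("NC")])
        np.testing.assert_array_equal(nc.centroid_size, sym.centroid_size)

    def test_modules_partition_the_joint_fit(self, small_sim):
        sym, mmap = small_sim["sym"], small_sim["module_map"]
        nc = mm.subset_module(sym, mmap, "NC")
        md = mm.subset_module(sym, mmap, "MD")
        rebuilt = np.empty_like(sym.aligned)
        rebuilt[:, mmap.indices("NC")] = nc.aligned
        rebuilt[:, mmap.indices("MD")] = md.aligned
        np.testing.assert_array_equal(rebuilt, sym.aligned)

    def test_refitting_a_subset_changes_coordinates(self, small_sim):
        sym, mmap = small_sim["sym"], small_sim["module_map"]
        nc = mm.subset_module(sym, mmap, "NC")
        refit = mm.gpa(nc.aligned)
        assert not np.allclose(refit.aligned, nc.aligned, atol=1e-6)
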