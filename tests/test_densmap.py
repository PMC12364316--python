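"""Density simulation, masked CC and gradient correctness."""

import math

import numpy as np
import pytest

from emligfit.densmap import (MapSimParams, cc_with_gradient, cross_correlation,
                              entity_cc, grid_like, resample_onto,
                              simulate_density, support_mask)
from emligfit.structio import Atom, DensityGrid, Selection, Structure

from conftest import random_structure


def single_atom(pos, element="C"):
    return Structure([Atom(1, element, element, "LIG", 1, "A", pos,
                           is_hetero=True)])


class TestSimulateDensity:
    def test_peak_matches_closed_form(self):
        """A single atom at a voxel centre gives the 3-D Gaussian peak."""
        st = single_atom([5.0, 5.0, 5.0])
        grid = DensityGrid([0, 0, 0], [1, 1, 1], np.zeros((11, 11, 11)))
        params = MapSimParams(resolution=3.2, amplitude_mode="uniform",
                              grid_spec=grid)
        d = simulate_density(st, Selection([0]), params)
        peak = 1.0 / ((2 * math.pi) ** 1.5 * params.sigma ** 3)
        assert d.values[5, 5, 5] == pytest.approx(peak, abs=1e-6)
        assert d.values.argmax() == np.ravel_multi_index((5, 5, 5), d.dims)

    def test_two_atoms_sum_linearly(self):
        grid = DensityGrid([0, 0, 0], [1, 1, 1], np.zeros((16, 16, 16)))
        params = MapSimParams(resolution=3.0, amplitude_mode="uniform",
                              grid_spec=grid)
        a = single_atom([5.0, 7.0, 8.0])
        b = single_atom([9.0, 7.5, 6.0])
        both = Structure(a.atoms + [Atom(2, "C", "C", "LIG", 2, "A",
                                         [9.0, 7.5, 6.0], is_hetero=True)])
        da = simulate_density(a, Selection([0]), params).values
        db = simulate_density(b, Selection([0]), params).values
        dab = simulate_density(both, Selection([0, 1]), params).values
        assert np.allclose(dab, da + db, atol=1e-12)

    def test_total_amplitude_conserved(self):
        """sum(values) * voxel volume ~ total amplitude (Gaussian norm)."""
        grid = DensityGrid([0, 0, 0], [1, 1, 1], np.zeros((24, 24, 24)))
        params = MapSimParams(resolution=3.2, amplitude_mode="uniform",
                              grid_spec=grid)
        st = random_structure(5, seed=2, lo=8, hi=16)
        d = simulate_density(st, Selection(np.arange(5)), params)
        assert d.values.sum() * 1.0 == pytest.approx(5.0, rel=0.01)

    def test_atomic_number_amplitudes(self):
        grid = DensityGrid([0, 0, 0], [1, 1, 1], np.zeros((11, 11, 11)))
        params = MapSimParams(resolution=3.2, grid_spec=grid)  # default mode
        c = simulate_density(single_atom([5, 5, 5], "C"), Selection([0]), params)
        o = simulate_density(single_atom([5, 5, 5], "O"), Selection([0]), params)
        assert o.values[5, 5, 5] / c.values[5, 5, 5] == pytest.approx(8 / 6)

    def test_empty_selection_rejected(self):
        st = single_atom([5, 5, 5])
        grid = DensityGrid([0, 0, 0], [1, 1, 1], np.zeros((8, 8, 8)))
        params = MapSimParams(resolution=3.0, grid_spec=grid)
        with pytest.raises(ValueError):
            simulate_density(st, Selection(np.array([], dtype=int)), params)

    def test_whole_voxel_translation_equivariance(self):
        st = random_structure(8, seed=5, lo=10, hi=18)
        grid = DensityGrid([0, 0, 0], [1, 1, 1], np.zeros((30, 30, 30)))
        params = MapSimParams(resolution=3.0, grid_spec=grid)
        sel = Selection(np.arange(8))
        d0 = simulate_density(st, sel, params).values
        shifted = st.with_coords(st.coords() + np.array([2.0, 0.0, 0.0]))
        d1 = simulate_density(shifted, sel, params).values
        assert np.allclose(d1[2:, :, :], d0[:-2, :, :], atol=1e-12)


class TestCrossCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        g = DensityGrid([0, 0, 0], [1, 1, 1], rng.normal(size=(6, 6, 6)))
        assert cross_correlation(g, g).cc == pytest.approx(1.0)
        neg = DensityGrid([0, 0, 0], [1, 1, 1], -g.values)
        assert cross_correlation(g, neg).cc == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        a = DensityGrid([0, 0, 0], [1, 1, 1], rng.normal(size=(6, 6, 6)))
        b = DensityGrid([0, 0, 0], [1, 1, 1], rng.normal(size=(6, 6, 6)))
        cc0 = cross_correlation(a, b).cc
        a2 = DensityGrid([0, 0, 0], [1, 1, 1], 3.7 * a.values + 1.4)
        assert cross_correlation(a2, b).cc == pytest.approx(cc0, abs=1e-12)

    def test_matches_naive_masked_pearson(self):
        """Displaced-copy cc equals an independent direct-summation oracle."""
        st = random_structure(12, seed=9, lo=8, hi=20)
        grid = DensityGrid([0, 0, 0], [1, 1, 1], np.zeros((30, 30, 30)))
        params = MapSimParams(resolution=3.0, grid_spec=grid)
        sel = Selection(np.arange(12))
        target = simulate_density(st, sel, params)
        moved = st.with_coords(st.coords() + np.array([2.0, 0.7, -0.4]))
        model = simulate_density(moved, sel, params)
        mask = support_mask(moved, sel, target, params)
        result = cross_correlation(model, target, mask=mask)

        # naive double loop over masked voxels
        f = []
        g = []
        for i in range(30):
            for j in range(30):
                for k in range(30):
                    if mask[i, j, k]:
                        f.append(model.values[i, j, k])
                        g.append(target.values[i, j, k])
        f = np.array(f) - np.mean(f)
        g = np.array(g) - np.mean(g)
        naive = float(f @ g / np.sqrt((f @ f) * (g @ g)))
        assert result.cc == pytest.approx(naive, abs=1e-12)
        assert result.mask_voxels == int(mask.sum())

    def test_degenerate_mask_rejected(self):
        g = DensityGrid([0, 0, 0], [1, 1, 1], np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="degenerate|variance"):
            cross_correlation(g, g, mask=np.ones((5, 5, 5), dtype=bool))
        with pytest.raises(ValueError, match="degenerate|mask"):
            cross_correlation(g, g, mask=np.zeros((5, 5, 5), dtype=bool))

    def test_geometry_mismatch_rejected(self):
        a = DensityGrid([0, 0, 0], [1, 1, 1], np.ones((5, 5, 5)))
        b = DensityGrid([0, 0, 0], [1, 1, 1], np.ones((6, 6, 6)))
        with pytest.raises(ValueError, match="geometry|resample"):
            cross_correlation(a, b)


class TestEntityCC:
    def test_full_context_scores_one_at_ground_truth(self, gt_map_and_params):
        """With the full model simulated over each entity's mask, a perfect
        model scores exactly 1 for every entity (local-fit variant)."""
        from emligfit.structio import (protein_selection, select_ligand,
                                       select_pocket)
        st, target, params = gt_map_and_params
        lig = select_ligand(st, "auto")
        for sel in (lig, select_pocket(st, lig), protein_selection(st)):
            cc = entity_cc(st, sel, target, params, context="full").cc
            assert cc == pytest.approx(1.0)

    def test_entity_only_self_cc_below_one_near_neighbours(self,
                                                           gt_map_and_params):
        """Per-entity CC of the true ligand stays below 1: protein density
        inside the ligand mask is unexplained by the ligand alone."""
        from emligfit.structio import protein_selection, select_ligand
        st, target, params = gt_map_and_params
        lig = select_ligand(st, "auto")
        lig_cc = entity_cc(st, lig, target, params).cc
        assert 0.3 < lig_cc < 0.9
        # the protein dominates the map, so its entity-only self-cc is high
        assert entity_cc(st, protein_selection(st), target, params).cc > 0.9

    def test_displaced_ligand_low_cc_protein_unchanged(self, gt_map_and_params):
        from emligfit.structio import protein_selection, select_ligand
        st, target, params = gt_map_and_params
        lig = select_ligand(st, "auto")
        coords = st.coords()
        coords[lig.indices] += np.array([11.0, 0.0, 0.0])
        moved = st.with_coords(coords)
        self_cc = entity_cc(st, lig, target, params).cc
        assert entity_cc(moved, lig, target, params).cc < 0.3 * self_cc
        prot_cc = entity_cc(moved, protein_selection(st), target, params).cc
        assert prot_cc > 0.9

    def test_cc_decreases_with_displacement(self, gt_map_and_params):
        from emligfit.structio import select_ligand
        st, target, params = gt_map_and_params
        lig = select_ligand(st, "auto")
        ccs = []
        for dz in (0.0, 1.0, 2.0, 3.0, 4.5, 6.0):
            coords = st.coords()
            coords[lig.indices] += np.array([0.0, 0.0, dz])
            ccs.append(entity_cc(st.with_coords(coords), lig, target,
                                 params).cc)
        assert all(a > b for a, b in zip(ccs, ccs[1:]))


class TestGradient:
    def test_zero_at_perfect_fit(self):
        st = random_structure(10, seed=4, lo=8, hi=20)
        grid = DensityGrid([0, 0, 0], [1, 1, 1], np.zeros((30, 30, 30)))
        params = MapSimParams(resolution=3.0, grid_spec=grid)
        sel = Selection(np.arange(10))
        target = simulate_density(st, sel, params)
        cc, grad = cc_with_gradient(st, sel, target, params)
        assert cc == pytest.approx(1.0)
        assert np.linalg.norm(grad, axis=1).max() < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, seed):
        """The module's central oracle: central FD with h = 1e-4 A."""
        rng = np.random.default_rng(seed)
        st = random_structure(10, seed=seed + 20, lo=8, hi=20)
        grid = DensityGrid([0, 0, 0], [1, 1, 1],
                           rng.normal(size=(30, 30, 30)))
        params = MapSimParams(resolution=3.0, grid_spec=grid,
                              truncation_radius=6.0)
        sel = Selection(np.arange(10))
        mask = support_mask(st, sel, grid, params)
        cc0, grad = cc_with_gradient(st, sel, grid, params, mask=mask)
        h = 1e-4
        coords = st.coords()
        for i in range(10):
            for d in range(3):
                cp = coords.copy()
                cp[i, d] += h
                cm = coords.copy()
                cm[i, d] -= h
                ccp, _ = cc_with_gradient(st.with_coords(cp), sel, grid,
                                          params, mask=mask)
                ccm, _ = cc_with_gradient(st.with_coords(cm), sel, grid,
                                          params, mask=mask)
                fd = (ccp - ccm) / (2 * h)
                assert grad[i, d] == pytest.approx(fd, rel=1e-4, abs=2e-7)

    def test_restoring_direction(self):
        """Model displaced +x from its density feels a -x mean gradient."""
        st = random_structure(8, seed=6, lo=10, hi=18)
        grid = DensityGrid([0, 0, 0], [1, 1, 1], np.zeros((30, 30, 30)))
        params = MapSimParams(resolution=3.0, grid_spec=grid)
        sel = Selection(np.arange(8))
        target = simulate_density(st, sel, params)
        moved = st.with_coords(st.coords() + np.array([2.0, 0.0, 0.0]))
        _, grad = cc_with_gradient(moved, sel, target, params)
        assert grad.sum(axis=0)[0] < 0


class TestResample:
    def test_identity(self):
        rng = np.random.default_rng(2)
        g = DensityGrid([1, 2, 3], [1, 1, 1], rng.normal(size=(8, 8, 8)))
        r = resample_onto(g, g)
        assert np.allclose(r.values, g.values, atol=1e-12)

    def test_constant_stays_constant(self):
        g = DensityGrid([0, 0, 0], [1, 1, 1], np.full((10, 10, 10), 3.3))
        ref = DensityGrid([1.2, 1.7, 0.3], [0.7, 0.7, 0.7],
                          np.zeros((8, 8, 8)))
        r = resample_onto(g, ref)
        assert np.allclose(r.values, 3.3)

    def test_down_up_sample_smooth_field(self):
        """Coarse-then-fine resampling of a smooth Gaussian: small RMS error."""
        st = single_atom([10.0, 10.0, 10.0])
        fine = DensityGrid([0, 0, 0], [0.5, 0.5, 0.5], np.zeros((41, 41, 41)))
        params = MapSimParams(resolution=4.0, amplitude_mode="uniform",
                              grid_spec=fine)
        d_fine = simulate_density(st, Selection([0]), params)
        coarse_ref = DensityGrid([0, 0, 0], [1.0, 1.0, 1.0],
                                 np.zeros((21, 21, 21)))
        coarse = resample_onto(d_fine, coarse_ref)
        back = resample_onto(coarse, fine)
        inner = (slice(4, -4),) * 3   # edge voxels lose support on the way
        err = np.sqrt(np.mean((back.values[inner]
                               - d_fine.values[inner]) ** 2))
        assert err < 0.02 * d_fine.values.max()

    def test_zero_overlap_rejected(self):
        a = DensityGrid([0, 0, 0], [1, 1, 1], np.ones((5, 5, 5)))
        b = DensityGrid([100, 100, 100], [1, 1, 1], np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="overlap"):
            resample_onto(a, b)
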