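"""Dye-center sampling, constraint bounds, superposition and apex relaxation."""

import numpy as np
import pytest

from stimfret.forster import fret_to_distance
from stimfret.structure import (
    CY3_LIKE,
    AtomicModel,
    DistanceConstraint,
    DyeParams,
    apply_apex_rotation,
    constraint_bounds,
    default_apex_constraints,
    effective_center,
    optimize_apex,
    read_constraints,
    sample_dye_centers,
    superpose,
    symmetrize_dimer,
    symmetry_residual,
    write_constraints,
)
from stimfret.synthetic import make_synthetic_cad


def _single_atom_model():
    return AtomicModel(
        element=np.array(["C"]),
        atom_name=np.array(["CA"]),
        res_id=np.array([1]),
        chain_id=np.array(["A"]),
        coord=np.zeros((1, 3)),
    )


class TestDyeSampling:
    def test_unclashed_mean_protrusion_is_three_quarters_tether(self):
        # E[r] of uniform sampling in a ball of radius L is 3L/4
        model = _single_atom_model()
        params = DyeParams(tether_length=1.2, n_samples=4000, min_ca_distance=0.0,
                           seed=3)
        cloud = sample_dye_centers(model, 1, "A", params)
        assert cloud.mean_protrusion == pytest.approx(0.9, abs=0.02)

    def test_wall_pushes_mean_center_away(self):
        # an impenetrable half-space: a thick slab of atoms below z = 0
        xs, ys, zs = np.meshgrid(
            np.arange(-2, 2.1, 0.2), np.arange(-2, 2.1, 0.2),
            np.arange(-1.45, -0.2, 0.4),
        )
        wall = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
        n = len(wall) + 1
        model = AtomicModel(
            element=np.full(n, "C"),
            atom_name=np.array(["CA"] + ["O"] * len(wall)),
            res_id=np.arange(n),
            chain_id=np.full(n, "A"),
            coord=np.vstack([np.zeros(3), wall]),
        )
        cloud = sample_dye_centers(model, 0, "A", DyeParams(n_samples=500, seed=1))
        assert cloud.mean_center[2] > 0.1  # displaced along +z, off the wall

    def test_fixed_seed_reproducible(self):
        model = _single_atom_model()
        a = sample_dye_centers(model, 1, "A", CY3_LIKE)
        b = sample_dye_centers(model, 1, "A", CY3_LIKE)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_buried_site_raises(self):
        # cage the attachment point tightly
        grid = np.mgrid[-1.5:1.6:0.25, -1.5:1.6:0.25, -1.5:1.6:0.25].reshape(3, -1).T
        cage = grid[np.linalg.norm(grid, axis=1) > 0.1]
        n = len(cage) + 1
        model = AtomicModel(
            element=np.full(n, "C"),
            atom_name=np.array(["CA"] + ["O"] * len(cage)),
            res_id=np.arange(n),
            chain_id=np.full(n, "A"),
            coord=np.vstack([np.zeros(3), cage]),
        )
        with pytest.raises(RuntimeError, match="buried"):
            sample_dye_centers(model, 0, "A", DyeParams(n_samples=200, seed=1))

    def test_effective_center_is_midpoint(self):
        a, b = np.zeros(3), np.array([0.2, 0.0, 0.0])
        np.testing.assert_allclose(effective_center(a, b), [0.1, 0, 0])
        np.testing.assert_allclose(effective_center(a, a), a)


class TestConstraintBounds:
    def test_cc1_cad_window(self):
        c = DistanceConstraint(site_a=(250, "A"), site_b=(400, "B"),
                               pair_class="cc1_cad", e_peak=0.5)
        c = constraint_bounds(c)
        assert c.d_fret == pytest.approx(5.1)
        assert c.lb == pytest.approx(fret_to_distance(0.55) - 1.0, abs=1e-9)
        assert c.ub == pytest.approx(fret_to_distance(0.45), abs=1e-9)
        assert c.lb == pytest.approx(3.93, abs=0.01)
        assert c.ub == pytest.approx(5.27, abs=0.01)

    def test_cc1_cc1_lower_bound_one_nm_deeper(self):
        kw = dict(site_a=(250, "A"), site_b=(250, "B"), e_peak=0.5)
        c1 = constraint_bounds(DistanceConstraint(pair_class="cc1_cad", **kw))
        c2 = constraint_bounds(DistanceConstraint(pair_class="cc1_cc1", **kw))
        assert c2.lb == pytest.approx(c1.lb - 1.0)
        assert c2.ub == c1.ub

    def test_degenerate_width(self):
        c = DistanceConstraint(site_a=(250, "A"), site_b=(250, "B"),
                               pair_class="cad_cad_inter", e_peak=0.5,
                               e_uncertainty=0.0)
        c = constraint_bounds(c)
        assert c.lb == pytest.approx(c.d_fret)
        assert c.ub == pytest.approx(c.d_fret)

    def test_widths_grow_with_uncertainty(self):
        widths = []
        for du in (0.02, 0.05, 0.10):
            c = constraint_bounds(
                DistanceConstraint(site_a=(250, "A"), site_b=(250, "B"),
                                   pair_class="cad_cad_inter", e_peak=0.5,
                                   e_uncertainty=du)
            )
            widths.append(c.ub - c.lb)
        assert widths[0] < widths[1] < widths[2]

    def test_bounds_bracket_d_fret(self):
        for e in (0.1, 0.3, 0.5, 0.7, 0.9):
            c = constraint_bounds(
                DistanceConstraint(site_a=(250, "A"), site_b=(250, "B"),
                                   pair_class="intra_subunit", e_peak=e)
            )
            assert c.lb <= c.d_fret <= c.ub

    def test_unknown_pair_class_rejected(self):
        with pytest.raises(ValueError, match="pair class"):
            DistanceConstraint(site_a=(1, "A"), site_b=(2, "B"),
                               pair_class="bogus", e_peak=0.5)

    def test_tsv_round_trip(self, tmp_path):
        cons = [
            DistanceConstraint(site_a=(239, "A"), site_b=(239, "B"),
                               pair_class="cc1_cc1", e_peak=0.42),
            DistanceConstraint(site_a=(300, "A"), site_b=(389, "B"),
                               pair_class="cc1_cad", e_peak=0.81),
        ]
        path = tmp_path / "constraints.tsv"
        write_constraints(cons, path)
        back = read_constraints(path)
        assert [(c.site_a, c.site_b, c.pair_class, c.e_peak) for c in back] == [
            (c.site_a, c.site_b, c.pair_class, c.e_peak) for c in cons
        ]


class TestSuperposition:
    def test_planted_rigid_transform_recovered(self, rng):
        pts = rng.normal(size=(6, 3))
        from scipy.spatial.transform import Rotation

        rot_true = Rotation.from_euler("xyz", [0.3, -0.5, 1.1]).as_matrix()
        trans_true = np.array([1.0, -2.0, 0.5])
        moved = pts @ rot_true.T + trans_true
        rot, trans, rmsd = superpose(pts, moved)
        np.testing.assert_allclose(rot, rot_true, atol=1e-9)
        np.testing.assert_allclose(trans, trans_true, atol=1e-9)
        assert rmsd < 1e-9

    def test_three_point_minimum(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSymmetrize:
    def test_output_invariant_under_returned_transform(self):
        cad = make_synthetic_cad()
        sym, tr = symmetrize_dimer(cad)
        assert symmetry_residual(sym, tr) < 1e-9

    def test_perturbed_chain_b_replaced_by_chain_a_copy(self):
        cad = make_synthetic_cad()
        b = cad.chain_mask("B")
        cad.coord[b] += np.array([0.05, 0.0, 0.0])  # asymmetric perturbation
        sym, tr = symmetrize_dimer(cad)
        assert symmetry_residual(sym, tr) < 1e-9

    def test_missing_alignment_residues_reported(self):
        cad = make_synthetic_cad()
        keep = ~((cad.res_id == 350) & (cad.chain_id == "B"))
        trimmed = AtomicModel(
            element=cad.element[keep], atom_name=cad.atom_name[keep],
            res_id=cad.res_id[keep], chain_id=cad.chain_id[keep],
            coord=cad.coord[keep],
        )
        with pytest.raises(ValueError, match="350"):
            symmetrize_dimer(trimmed)


class TestApex:
    @pytest.fixture(scope="class")
    def symmetric(self):
        return symmetrize_dimer(make_synthetic_cad())

    def test_self_consistent_constraints_give_identity(self, symmetric):
        sym, tr = symmetric
        res = optimize_apex(sym, tr, default_apex_constraints(sym))
        assert np.degrees(res.tilt_angle) == pytest.approx(0.0, abs=1.0)
        assert res.objective < 1e-4

    def test_planted_rotation_recovered(self, symmetric):
        sym, tr = symmetric
        planted = apply_apex_rotation(sym, tr, psi=1.0, theta=np.deg2rad(30))
        res = optimize_apex(sym, tr, default_apex_constraints(planted))
        assert np.degrees(res.tilt_angle) == pytest.approx(30.0, abs=5.0)
        assert max(abs(v) for v in res.residuals.values()) < 0.05

    def test_asymmetric_input_rejected(self, symmetric):
        sym, tr = symmetric
        broken = sym.copy()
        broken.coord[broken.chain_mask("B")] += 0.05
        with pytest.raises(ValueError, match="symmetrize"):
            optimize_apex(broken, tr, default_apex_constraints(sym))
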