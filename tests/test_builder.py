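"""CC1 chain growth: constraints, backtracking, relaxation, ensembles."""

import numpy as np
import pytest

from stimfret.builder import (
    BuilderConfig,
    BuildFailure,
    build_chain_solution,
    average_model,
    classify_topology,
    ensemble_build,
    relax_and_build,
)
from stimfret.chain import CC1_HELIX_RANGES, NodeChain
from stimfret.structure import (
    AtomicModel,
    DistanceConstraint,
    SymmetryTransform,
    constraint_bounds,
)
from stimfret.synthetic import make_planted_constraints
from stimfret.validate import validate_solution


def _empty_cad(anchor=(2.0, 1.0, 0.0), start=344):
    """A minimal anchor-only 'CAD': one atom per chain at the start residue."""
    t = SymmetryTransform(rotation=np.diag([-1.0, -1.0, 1.0]), translation=np.zeros(3))
    a = np.asarray(anchor, float)
    return (
        AtomicModel(
            element=np.array(["C", "C"]),
            atom_name=np.array(["CA", "CA"]),
            res_id=np.array([start, start]),
            chain_id=np.array(["A", "B"]),
            coord=np.vstack([a, t.apply(a)]),
        ),
        t,
    )


def _linker_config(n_residues=10, **kw):
    """A short pure-linker chain config (no helices)."""
    defaults = dict(
        helix_ranges={}, start_residue=344, end_residue=344 - n_residues,
        n_solutions=2, seed=0,
    )
    defaults.update(kw)
    return BuilderConfig(**defaults)


class TestGrowth:
    def test_unconstrained_linker_always_succeeds(self):
        cad, tr = _empty_cad()
        cfg = _linker_config()
        for seed in range(10):
            sol = build_chain_solution(cad, [], cfg, tr, seed=seed)
            assert isinstance(sol, NodeChain)
            steps = np.diff(sol.coords_a, axis=0)
            np.testing.assert_allclose(np.linalg.norm(steps, axis=1), 0.38, atol=1e-9)
            dirs = steps / np.linalg.norm(steps, axis=1, keepdims=True)
            dots = np.einsum("ij,ij->i", dirs[:-1], dirs[1:])
            assert np.all(dots >= -1e-9)  # never turns by more than 90°

    def test_impossible_upper_bound_reports_deepest_residue(self):
        cad, tr = _empty_cad()
        cfg = _linker_config(max_backtracks=20)
        # two same-chain sites must approach closer than the steric
        # exclusion radius permits: unsatisfiable by construction
        con = constraint_bounds(
            DistanceConstraint(site_a=(343, "A"), site_b=(339, "A"),
                               pair_class="intra_subunit", e_peak=0.999)
        )
        con.lb, con.ub = 0.0, 0.2
        assert con.ub < 0.25
        result = build_chain_solution(cad, [con], cfg, tr, seed=1)
        assert isinstance(result, BuildFailure)
        assert result.deepest_residue <= 340
        assert result.rejection_counts

    def test_planted_constraints_are_buildable(self, cad_model, cad_transform,
                                               planted_chain):
        cons = [
            constraint_bounds(c)
            for c in make_planted_constraints(planted_chain, cad_model, jitter=0.0)
        ]
        cfg = BuilderConfig(seed=0)
        successes = 0
        for seed in range(6):
            result = build_chain_solution(cad_model, cons, cfg, cad_transform,
                                          seed=seed)
            if isinstance(result, NodeChain):
                successes += 1
                report = validate_solution(result, cad_model, cons, cfg)
                assert report.ok, report.problems
        assert successes > 0


class TestRelaxation:
    def test_feasible_set_needs_no_relaxation(self):
        cad, tr = _empty_cad()
        cfg = _linker_config()
        cons, sol = relax_and_build(cad, [], cfg, tr)
        assert isinstance(sol, NodeChain)
        assert cons == []

    def test_overtight_constraint_relaxed_until_feasible(self):
        cad, tr = _empty_cad()
        cfg = _linker_config(n_residues=6, max_backtracks=30,
                             attempts_per_relaxation=2, seed=2)
        # 334:334' inter-subunit distance is at least 2*|anchor_xy| - ... ;
        # make the window ~2 nm too tight so two 1-nm relaxations are needed
        con = DistanceConstraint(site_a=(340, "A"), site_b=(340, "B"),
                                 pair_class="cc1_cc1", e_peak=0.5)
        con = constraint_bounds(con)
        min_reach = 2 * np.hypot(2.0, 1.0) - 2 * 4 * 0.38  # anchor symmetry limit
        con.lb = 0.0
        con.ub = max(min_reach - 2.0, 0.05)
        cons, sol = relax_and_build(cad, [con], cfg, tr)
        assert isinstance(sol, NodeChain)
        assert cons[0].n_relaxations >= 2

    def test_empty_constraints_immediate_success(self):
        cad, tr = _empty_cad()
        cons, sol = relax_and_build(cad, [], _linker_config(), tr)
        assert isinstance(sol, NodeChain)


class TestEnsemble:
    def test_seeded_ensemble_is_reproducible(self):
        cad, tr = _empty_cad()
        cfg = _linker_config(n_solutions=2, seed=5)
        a = ensemble_build(cad, [], cfg, tr)
        b = ensemble_build(cad, [], _linker_config(n_solutions=2, seed=5), tr)
        for sa, sb in zip(a.solutions, b.solutions):
            np.testing.assert_array_equal(sa.coords_a, sb.coords_a)

    def test_unconstrained_ensemble_is_diverse(self):
        cad, tr = _empty_cad()
        ens = ensemble_build(cad, [], _linker_config(n_solutions=3, seed=1), tr)
        rmsd = np.sqrt(
            np.mean((ens.solutions[0].coords_a - ens.solutions[1].coords_a) ** 2)
        )
        assert rmsd > 0.01


class TestAveraging:
    def _solution(self, coords, residues, tr):
        return NodeChain(residues=residues, coords_a=coords,
                         coords_b=tr.apply(coords), transform=tr, kind="solution")

    def test_identical_solutions_average_to_themselves(self):
        cad, tr = _empty_cad()
        sol = build_chain_solution(cad, [], _linker_config(), tr, seed=3)
        avg = average_model([sol, sol], force=True)
        np.testing.assert_allclose(avg.coords_a, sol.coords_a)
        np.testing.assert_allclose(avg.spread, 0.0, atol=1e-12)
        assert avg.kind == "average"

    def test_isotropic_noise_spread_recovers_sigma(self, rng):
        tr = SymmetryTransform(rotation=np.diag([-1.0, -1.0, 1.0]),
                               translation=np.zeros(3))
        base = rng.normal(size=(20, 3))
        residues = np.arange(344, 324, -1)
        sigma = 0.3
        sols = [
            self._solution(base + rng.normal(0, sigma, base.shape), residues, tr)
            for _ in range(200)
        ]
        avg = average_model(sols, force=True)
        # per-residue RMS spread of isotropic 3-D noise is sigma * sqrt(3)
        assert np.mean(avg.spread) == pytest.approx(sigma * np.sqrt(3), rel=0.2)

    def test_single_solution_rejected(self):
        cad, tr = _empty_cad()
        sol = build_chain_solution(cad, [], _linker_config(), tr, seed=3)
        with pytest.raises(ValueError):
            average_model([sol])


class TestTopology:
    def _chain_with_helices(self, a2_dir, a2_origin):
        """Hand-built chain whose CC1α3 rises along +z near the axis."""
        tr = SymmetryTransform(rotation=np.diag([-1.0, -1.0, 1.0]),
                               translation=np.zeros(3))
        residues = np.arange(344, 232, -1)
        coords = np.zeros((len(residues), 3))
        for i, r in enumerate(residues):
            coords[i] = [3.0, 3.0, 0.01 * i]  # filler far away
        a3_lo, a3_hi = CC1_HELIX_RANGES["CC1a3"]
        for r in range(a3_lo, a3_hi + 1):
            i = int(np.flatnonzero(residues == r)[0])
            coords[i] = [0.4, 0.4, (r - a3_lo) * 0.15]
        a2_lo, a2_hi = CC1_HELIX_RANGES["CC1a2"]
        d = np.asarray(a2_dir, float)
        d /= np.linalg.norm(d)
        for r in range(a2_lo, a2_hi + 1):
            i = int(np.flatnonzero(residues == r)[0])
            coords[i] = np.asarray(a2_origin, float) + (r - a2_lo) * 0.15 * d
        return NodeChain(residues=residues, coords_a=coords,
                         coords_b=tr.apply(coords), transform=tr)

    def test_antiparallel_close_pair_is_stacked(self):
        # partner CC1α3' rises at (-0.4, -0.4); run CC1α2 down right next to it
        chain = self._chain_with_helices(a2_dir=(0, 0, -1),
                                         a2_origin=(-0.4, -1.0, 4.0))
        label, diag = classify_topology(chain)
        assert label == "stacked"
        assert diag["axis_angle_deg"] > 135
        assert diag["min_axis_distance_nm"] < 1.5

    def test_perpendicular_distant_pair_is_wedged(self):
        chain = self._chain_with_helices(a2_dir=(1, 0, 0),
                                         a2_origin=(2.0, -3.0, 1.0))
        label, diag = classify_topology(chain)
        assert label == "wedged"

    def test_classification_is_deterministic(self):
        chain = self._chain_with_helices(a2_dir=(0, 0, -1),
                                         a2_origin=(-0.4, -1.0, 4.0))
        labels = {classify_topology(chain)[0] for _ in range(5)}
        assert len(labels) == 1
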