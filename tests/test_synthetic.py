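"""Ground-truth generators: state paths, trace rendering, defects, constraints."""

import numpy as np
import pytest

from stimfret.chain import CC1_HELIX_RANGES, step_spacing
from stimfret.forster import distance_to_fret
from stimfret.structure import constraint_bounds
from stimfret.synthetic import (
    SimulationConfig,
    make_planted_constraints,
    plant_defects,
    render_trace_set,
    simulate_state_paths,
)
from stimfret.validate import validate_solution


def _noiseless(**kw):
    base = dict(
        poisson_noise=False, read_noise_sd=0.0, excitation_noise_sd=0.0, leakage=0.0
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestStatePaths:
    def test_single_state_is_constant(self):
        cfg = _noiseless(n_molecules=3, n_frames=50, state_means=(0.7,), seed=1)
        truth = simulate_state_paths(cfg)
        for m in truth:
            assert np.all(m.state_path == 0)
            assert np.all(m.true_e == 0.7)

    def test_zero_rates_never_leave_initial_state(self):
        q = np.zeros((2, 2))
        cfg = _noiseless(n_molecules=10, n_frames=100, state_means=(0.2, 0.8),
                         rate_matrix=q, seed=2)
        truth = simulate_state_paths(cfg)
        for m in truth:
            assert len(np.unique(m.state_path)) == 1

    def test_symmetric_two_state_occupancy_is_half(self):
        # stationary distribution of the symmetric chain is (1/2, 1/2)
        q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        cfg = _noiseless(n_molecules=10_000, n_frames=100, state_means=(0.2, 0.8),
                         rate_matrix=q, acceptor_bleach_rate=0, donor_bleach_rate=0,
                         seed=3)
        truth = simulate_state_paths(cfg)
        occ = np.mean([m.state_path.mean() for m in truth])
        assert occ == pytest.approx(0.5, abs=0.02)

    def test_reproducible_under_seed(self):
        cfg = SimulationConfig(n_molecules=5, n_frames=60, seed=7)
        a = simulate_state_paths(cfg)
        b = simulate_state_paths(SimulationConfig(n_molecules=5, n_frames=60, seed=7))
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.state_path, mb.state_path)
            assert ma.gamma_true == mb.gamma_true
            assert ma.acceptor_bleach_frame == mb.acceptor_bleach_frame

    def test_non_conservative_rate_matrix_rejected(self):
        with pytest.raises(ValueError, match="conservative"):
            SimulationConfig(state_means=(0.2, 0.8),
                             rate_matrix=np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestTraceRendering:
    def test_equal_channels_at_half_efficiency(self):
        cfg = _noiseless(n_molecules=2, n_frames=40, state_means=(0.5,),
                         gamma_sigma=0.0, acceptor_bleach_rate=0,
                         donor_bleach_rate=0, seed=1)
        truth = simulate_state_paths(cfg)
        for t in render_trace_set(truth):
            np.testing.assert_allclose(t.donor, t.acceptor)

    def test_gamma_inversion_recovers_efficiency(self):
        cfg = _noiseless(n_molecules=1, n_frames=30, state_means=(0.5,),
                         acceptor_bleach_rate=0, donor_bleach_rate=0, seed=1)
        truth = simulate_state_paths(cfg)
        truth.molecules[0].gamma_true = 2.0
        (t,) = render_trace_set(truth)
        np.testing.assert_allclose(t.acceptor / t.donor, 2.0)
        e = t.acceptor / (t.acceptor + 2.0 * t.donor)
        np.testing.assert_allclose(e, 0.5)

    def test_leakage_fraction_exact_at_zero_fret(self):
        cfg = _noiseless(n_molecules=1, n_frames=30, state_means=(1e-9,), leakage=0.07,
                         acceptor_bleach_rate=0, donor_bleach_rate=0, seed=1)
        truth = simulate_state_paths(cfg)
        (t,) = render_trace_set(truth)
        np.testing.assert_allclose(t.acceptor, 0.07 * t.donor, atol=1e-6)

    def test_noiseless_fret_equals_state_means(self):
        cfg = _noiseless(n_molecules=4, n_frames=120, state_means=(0.3, 0.9), seed=5)
        truth = simulate_state_paths(cfg)
        for m, t in zip(truth, render_trace_set(truth)):
            stop = min(m.acceptor_bleach_frame, cfg.n_frames)
            e = t.acceptor[:stop] / (
                t.acceptor[:stop] + m.gamma_true * t.donor[:stop]
            )
            np.testing.assert_allclose(e, m.true_e[:stop], atol=1e-12)


class TestDefects:
    def _truth(self, n=200, seed=3):
        cfg = SimulationConfig(n_molecules=n, n_frames=400, seed=seed)
        return simulate_state_paths(cfg)

    def test_zero_fractions_change_nothing(self):
        truth = plant_defects(self._truth(), {}, seed=1)
        assert all(m.defect == "clean" for m in truth)

    def test_counts_are_deterministic(self):
        truth = plant_defects(self._truth(), {"multi_step_bleach": 0.2}, seed=4)
        assert sum(m.defect == "multi_step_bleach" for m in truth) == 40

    def test_donor_first_swaps_bleach_order(self):
        truth = plant_defects(self._truth(n=50), {"donor_first": 1.0}, seed=4)
        for m in truth:
            assert m.donor_bleach_frame < m.acceptor_bleach_frame

    def test_labels_partition_molecules(self):
        truth = plant_defects(
            self._truth(), {"donor_first": 0.25, "uncorrelated": 0.25, "aggregate": 0.5},
            seed=4,
        )
        counts = {}
        for m in truth:
            counts[m.defect] = counts.get(m.defect, 0) + 1
        assert sum(counts.values()) == len(truth)
        assert counts.get("clean", 0) == 0

    def test_overcommitted_fractions_rejected(self):
        with pytest.raises(ValueError):
            plant_defects(self._truth(), {"donor_first": 0.7, "aggregate": 0.5}, seed=1)


class TestPlantedChain:
    def test_spacings_and_symmetry(self, planted_chain):
        res = planted_chain.residues
        a = planted_chain.coords_a
        for i in range(len(res) - 1):
            want = step_spacing(int(res[i]), int(res[i + 1]))
            assert np.linalg.norm(a[i + 1] - a[i]) == pytest.approx(want, abs=1e-9)
        mapped = planted_chain.transform.apply(a)
        assert np.max(np.linalg.norm(mapped - planted_chain.coords_b, axis=1)) < 1e-9

    def test_helices_are_straight(self, planted_chain):
        for name in CC1_HELIX_RANGES:
            nodes = planted_chain.helix_nodes(name)
            v = np.diff(nodes, axis=0)
            v = v / np.linalg.norm(v, axis=1, keepdims=True)
            assert np.max(np.abs(v - v[0])) < 1e-9


class TestPlantedConstraints:
    def test_forster_midpoint(self, planted_chain, cad_model):
        cons = make_planted_constraints(planted_chain, cad_model)
        for c in cons:
            # E must invert back to the true model distance
            assert 0.02 <= c.e_peak <= 0.98

    def test_known_distance_maps_to_known_efficiency(self):
        assert distance_to_fret(5.1) == pytest.approx(0.5, abs=1e-12)
        assert distance_to_fret(3.536) == pytest.approx(0.90, abs=1e-3)

    def test_zero_jitter_constraints_satisfied_by_planted_chain(
        self, planted_chain, cad_model
    ):
        from stimfret.builder import BuilderConfig

        cons = [
            constraint_bounds(c)
            for c in make_planted_constraints(planted_chain, cad_model, jitter=0.0)
        ]
        report = validate_solution(planted_chain, cad_model, cons, BuilderConfig())
        assert not [p for p in report.problems if "constraint" in p]

    def test_site_outside_chain_rejected(self, planted_chain, cad_model):
        with pytest.raises(ValueError, match="outside"):
            make_planted_constraints(
                planted_chain, cad_model,
                site_pairs=[((100, "A"), (100, "B"), "cc1_cc1")],
            )
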