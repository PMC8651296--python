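"""Channel registration, spot detection, colocalization, trace extraction."""

import numpy as np
import pytest

from stimfret.movies import (
    RegistrationMap,
    correct_background,
    detect_spots,
    estimate_registration,
    extract_traces,
    match_spots,
    process_movie,
    split_channels,
)
from stimfret.synthetic import (
    MovieConfig,
    SimulationConfig,
    assign_positions,
    render_movie,
    render_trace_set,
    simulate_state_paths,
)


def _gauss_spot(shape, x, y, amp=100.0, sigma=1.2):
    img = np.zeros(shape)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return img


class TestDetectSpots:
    def test_flat_image_yields_nothing(self):
        assert detect_spots(np.zeros((32, 32)), min_intensity=0.5) == []

    def test_single_spot_found_at_peak(self):
        img = _gauss_spot((32, 32), 10, 10)
        spots = detect_spots(img, min_intensity=10)
        assert len(spots) == 1
        assert spots[0].x == pytest.approx(10, abs=0.1)
        assert spots[0].y == pytest.approx(10, abs=0.1)

    def test_close_spots_keep_only_brighter(self):
        # 2 px apart, inside the 5-px-diameter strict-maximum neighborhood
        img = _gauss_spot((32, 32), 10, 10, amp=100) + _gauss_spot(
            (32, 32), 12, 10, amp=60
        )
        spots = detect_spots(img, min_intensity=10)
        assert len(spots) == 1
        assert abs(spots[0].x - 10) < 1.0

    def test_shift_invariance_with_matching_threshold(self):
        img = _gauss_spot((32, 32), 15, 9)
        a = detect_spots(img, min_intensity=5)
        b = detect_spots(img + 40.0, min_intensity=45)
        assert [(round(s.x), round(s.y)) for s in a] == [
            (round(s.x), round(s.y)) for s in b
        ]


class TestRegistration:
    def _bead_pair(self, matrix=np.eye(2), offset=(0.0, 0.0), n=9, seed=0):
        rng = np.random.default_rng(seed)
        img_d = np.zeros((64, 64))
        img_a = np.zeros((64, 64))
        for _ in range(n):
            x, y = rng.uniform(8, 56, 2)
            img_d += _gauss_spot(img_d.shape, x, y, amp=500)
            ax, ay = matrix @ (x, y) + offset
            img_a += _gauss_spot(img_a.shape, ax, ay, amp=500)
        return img_d, img_a

    def test_identical_images_give_identity(self):
        d, a = self._bead_pair()
        reg = estimate_registration(d, a)
        np.testing.assert_allclose(reg.matrix, np.eye(2), atol=5e-3)
        np.testing.assert_allclose(reg.offset, 0.0, atol=0.15)
        assert reg.residual_rms < 0.2

    def test_planted_translation_recovered(self):
        d, a = self._bead_pair(offset=(2.0, -1.5))
        reg = estimate_registration(d, a)
        np.testing.assert_allclose(reg.offset, [2.0, -1.5], atol=0.1)

    def test_planted_rotation_recovered(self):
        th = np.deg2rad(1.0)
        m = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        d, a = self._bead_pair(matrix=m, offset=(1.0, 0.5))
        reg = estimate_registration(d, a)
        np.testing.assert_allclose(reg.matrix, m, atol=1e-2)

    def test_too_few_beads_raises(self):
        d, a = self._bead_pair(n=2)
        with pytest.raises(ValueError):
            estimate_registration(d, a)

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError):
            RegistrationMap(matrix=np.zeros((2, 2)), offset=np.zeros(2),
                            residual_rms=0.0)


class TestMatching:
    def test_colocated_spots_all_match(self):
        from stimfret.movies import Spot

        spots = [Spot(10, 10, 1), Spot(30, 40, 1)]
        pairs = match_spots(spots, spots, RegistrationMap.identity())
        assert len(pairs) == 2

    def test_unmatched_donor_discarded(self):
        from stimfret.movies import Spot

        donor = [Spot(10, 10, 1), Spot(50, 50, 1)]
        acceptor = [Spot(10.2, 10.1, 1)]
        pairs = match_spots(donor, acceptor, RegistrationMap.identity())
        assert len(pairs) == 1
        assert pairs[0][0].x == 10

    def test_mutual_nearest_neighbor_keeps_only_closer(self):
        from stimfret.movies import Spot

        donor = [Spot(10.0, 10.0, 1), Spot(11.5, 10.0, 1)]
        acceptor = [Spot(10.2, 10.0, 1)]
        pairs = match_spots(donor, acceptor, RegistrationMap.identity())
        assert len(pairs) == 1
        assert pairs[0][0].x == 10.0


class TestExtraction:
    @pytest.fixture(scope="class")
    def noiseless_movie(self):
        cfg = SimulationConfig(
            n_molecules=8, n_frames=30, total_intensity=800, state_means=(0.4, 0.6),
            background_level=10.0, background_gradient=0.05,
            poisson_noise=False, read_noise_sd=0.0, excitation_noise_sd=0.0,
            acceptor_bleach_rate=0.02, donor_bleach_rate=0.02, seed=4,
        )
        truth = simulate_state_paths(cfg)
        mc = MovieConfig(misalignment_offset=np.array([2.0, -1.5]))
        truth = assign_positions(truth, mc)
        traces = render_trace_set(truth)
        stack, beads = render_movie(truth, traces, mc)
        return truth, traces, stack, beads

    def test_zero_movie_gives_zero_traces(self):
        from stimfret.movies import Spot

        stack = np.zeros((5, 16, 32))
        traces, _ = extract_traces(stack, [(Spot(8, 8, 0), Spot(8, 8, 0))])
        assert np.all(traces[0].donor == 0)
        assert np.all(traces[0].acceptor == 0)

    def test_rendering_conserves_intensity(self):
        cfg = SimulationConfig(
            n_molecules=1, n_frames=10, total_intensity=500, state_means=(0.5,),
            poisson_noise=False, read_noise_sd=0.0, excitation_noise_sd=0.0,
            acceptor_bleach_rate=0, donor_bleach_rate=0, seed=1,
        )
        truth = simulate_state_paths(cfg)
        mc = MovieConfig()
        truth = assign_positions(truth, mc)
        traces = render_trace_set(truth)
        stack, _ = render_movie(truth, traces, mc)
        donor_half, _ = split_channels(stack)
        np.testing.assert_allclose(
            donor_half.sum(axis=(1, 2)), traces[0].donor, rtol=1e-3
        )

    def test_end_to_end_extraction_tracks_ground_truth(self, noiseless_movie):
        truth, traces, stack, (bd, ba) = noiseless_movie
        out, reg, pairs = process_movie(stack, bd, ba, min_intensity=20)
        assert len(out) == len(truth)
        tm = {t.molecule_id: t for t in traces}
        for t, (sd, sa) in zip(out, pairs):
            m = min(truth.molecules,
                    key=lambda m: (m.donor_pos[0] - sd.x) ** 2 + (m.donor_pos[1] - sd.y) ** 2)
            ref = tm[m.molecule_id]
            mask = ref.donor > 50
            rel = np.abs(t.donor[mask] - ref.donor[mask]) / ref.donor[mask]
            # a 5x5 aperture truncates the PSF tails; background is removed
            assert rel.max() < 0.12

    def test_uniform_background_fully_subtracted(self):
        from stimfret.movies import Spot

        stack = np.full((4, 32, 64), 7.0)
        pairs = [(Spot(16, 16, 0), Spot(16, 16, 0))]
        raw, kept = extract_traces(stack, pairs)
        assert np.all(raw[0].donor == 7.0 * 25)
        corrected = correct_background(raw, stack, kept)
        np.testing.assert_allclose(corrected[0].donor, 0.0, atol=1e-9)

    def test_planted_misalignment_recovered(self, noiseless_movie):
        _, _, _, (bd, ba) = noiseless_movie
        reg = estimate_registration(bd, ba)
        np.testing.assert_allclose(reg.offset, [2.0, -1.5], atol=0.1)
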