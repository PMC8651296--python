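"""Ground-truth simulators for every stage of the pipeline.

Trace/movie side: k-state continuous-time Markov FRET dynamics sampled at
100 ms frames, Poisson shot noise plus Gaussian read noise, per-molecule
detection-efficiency ratio γ, 7% donor→acceptor spectral leakage,
single-step acceptor-then-donor photobleaching, background offsets and
gradients, and planted defect traces (multi-step bleaches, donor-first
bleaches, uncorrelated channels, aggregates with out-of-range γ).

Structure side: a synthetic CAD-like dimer (parallel V-shaped CC2/CC3
helix pair, residues 344–443, Cα geometry), a planted CC1 node chain in a
stacked configuration, and forward-simulated FRET distance-constraint
tables with known ground truth.  These stand in for the crystal-structure
and measured-constraint inputs of a real dataset and are labelled synthetic
throughout.

γ is modeled as an acceptor-side detection gain, so the intensity changes
across the acceptor bleach satisfy ΔI_A/ΔI_D = γ exactly in the noiseless
limit — the oracle used to test γ estimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from stimfret.chain import (
    CC1_END,
    CC1_START,
    HELIX_SPACING,
    LINKER_SPACING,
    NodeChain,
)
from stimfret.forster import ForsterConfig, distance_to_fret
from stimfret.structure import AtomicModel, DistanceConstraint, SymmetryTransform
from stimfret.traces import MoleculeTrace

#: planted chains are ordinary node chains with kind="planted"
PlantedChain = NodeChain

__all__ = [
    "SimulationConfig",
    "MoleculeGroundTruth",
    "GroundTruth",
    "simulate_state_paths",
    "render_trace_set",
    "plant_defects",
    "MovieConfig",
    "render_movie",
    "make_synthetic_cad",
    "PlantedChain",
    "make_planted_chain",
    "default_site_pairs",
    "make_planted_constraints",
]

DEFECT_LABELS = ("clean", "multi_step_bleach", "donor_first", "uncorrelated", "aggregate")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Study conditions for the trace/movie simulator.

    Defaults encode the measurement conditions emulated throughout: 100 ms
    frames, a predominant high-FRET state near 0.9 with transitions to a low
    state near 0.3 on a ~1 s timescale, per-molecule γ lognormal around 1
    spanning roughly 0.5–2.5, 7% leakage, and photobleaching within the
    recording window (acceptor typically before donor).
    """

    n_molecules: int = 100
    frame_interval: float = 0.1  # seconds
    n_frames: int = 400
    state_means: tuple = (0.3, 0.9)
    rate_matrix: np.ndarray | None = None  # per-second; default symmetric 0.5/s
    total_intensity: float = 400.0  # mean detected photons/frame
    gamma_sigma: float = 0.25  # lognormal spread of γ (median 1.0)
    gamma_range: tuple = (0.5, 2.5)  # clean molecules resampled into this range
    leakage: float = 0.07
    acceptor_bleach_rate: float = 0.05  # per second
    donor_bleach_rate: float = 0.05
    background_level: float = 0.0  # counts/pixel (movies)
    background_gradient: float = 0.0  # counts/pixel per pixel (movies)
    read_noise_sd: float = 2.0  # counts
    excitation_noise_sd: float = 0.03  # common-mode laser/focus fluctuation
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.state_means, dtype=float)
        if np.any(np.diff(means) <= 0):
            raise ValueError("state_means must be strictly increasing")
        if not 0.0 <= self.leakage < 1.0:
            raise ValueError("leakage must lie in [0, 1)")
        if self.acceptor_bleach_rate < 0 or self.donor_bleach_rate < 0:
            raise ValueError("bleach rates must be non-negative")
        if self.rate_matrix is None:
            k = len(means)
            q = np.full((k, k), 0.5) - 0.5 * k * np.eye(k) if k > 1 else np.zeros((1, 1))
            self.rate_matrix = q
        q = np.asarray(self.rate_matrix, dtype=float)
        if q.shape != (len(means), len(means)):
            raise ValueError("rate_matrix shape must match state_means")
        off = q[~np.eye(len(means), dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if not np.allclose(q.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("rate_matrix rows must sum to zero (conservative)")
        self.rate_matrix = q
        self.state_means = tuple(means)


@dataclass
class MoleculeGroundTruth:
    molecule_id: int
    state_path: np.ndarray  # state index per frame
    true_e: np.ndarray  # per-frame true FRET efficiency
    gamma_true: float
    acceptor_bleach_frame: int  # first dark acceptor frame (may exceed n_frames)
    donor_bleach_frame: int
    donor_pos: tuple = (0.0, 0.0)  # pixels in the donor half-image
    acceptor_pos: tuple = (0.0, 0.0)
    defect: str = "clean"
    overlapping: bool = False


@dataclass
class GroundTruth:
    config: SimulationConfig
    molecules: list

    def __iter__(self):
        return iter(self.molecules)

    def __len__(self):
        return len(self.molecules)

    def to_json(self, path) -> None:
        payload = {
            str(m.molecule_id): {
                "gamma_true": m.gamma_true,
                "acceptor_bleach_frame": int(m.acceptor_bleach_frame),
                "donor_bleach_frame": int(m.donor_bleach_frame),
                "donor_pos": list(map(float, m.donor_pos)),
                "acceptor_pos": list(map(float, m.acceptor_pos)),
                "defect": m.defect,
                "state_path": np.asarray(m.state_path).tolist(),
            }
            for m in self.molecules
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# state paths


def _stationary_distribution(q: np.ndarray) -> np.ndarray:
    k = q.shape[0]
    if k == 1 or np.allclose(q, 0):
        return np.full(k, 1.0 / k)
    a = np.vstack([q.T, np.ones(k)])
    b = np.concatenate([np.zeros(k), [1.0]])
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def _sample_ctmc_path(q, t_end, rng, initial):
    """Exact CTMC trajectory: (jump_times, states) with exponential waits."""
    times = [0.0]
    states = [initial]
    t = 0.0
    s = initial
    while True:
        rate_out = -q[s, s]
        if rate_out <= 0:
            break
        t += rng.exponential(1.0 / rate_out)
        if t >= t_end:
            break
        probs = q[s].copy()
        probs[s] = 0.0
        probs = probs / probs.sum()
        s = int(rng.choice(len(probs), p=probs))
        times.append(t)
        states.append(s)
    return np.array(times), np.array(states, dtype=int)


def _geometric_frame(rate: float, dt: float, rng) -> int:
    """Frame index of a memoryless per-frame event (∞ if rate is 0)."""
    if rate <= 0:
        return np.iinfo(np.int64).max // 4
    p = 1.0 - np.exp(-rate * dt)
    return int(rng.geometric(p))


def simulate_state_paths(config: SimulationConfig) -> GroundTruth:
    """Sample per-molecule Markov state paths, γ values and bleach frames.

    State dynamics are sampled exactly in continuous time and discretized by
    frame-start occupancy; bleach frames are geometric with the per-frame
    bleaching probability, the donor always bleaching after the acceptor for
    clean molecules.  Fully reproducible under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    q = config.rate_matrix
    means = np.asarray(config.state_means)
    pi = _stationary_distribution(q)
    dt = config.frame_interval
    frame_starts = np.arange(config.n_frames) * dt

    molecules = []
    for i in range(config.n_molecules):
        initial = int(rng.choice(len(means), p=pi))
        jt, js = _sample_ctmc_path(q, config.n_frames * dt, rng, initial)
        idx = np.searchsorted(jt, frame_starts, side="right") - 1
        path = js[idx]
        while True:
            gamma = float(np.exp(rng.normal(0.0, config.gamma_sigma)))
            if config.gamma_range[0] <= gamma <= config.gamma_range[1]:
                break
        f_a = _geometric_frame(config.acceptor_bleach_rate, dt, rng)
        f_d = f_a + _geometric_frame(config.donor_bleach_rate, dt, rng)
        molecules.append(
            MoleculeGroundTruth(
                molecule_id=i,
                state_path=path,
                true_e=means[path],
                gamma_true=gamma,
                acceptor_bleach_frame=f_a,
                donor_bleach_frame=f_d,
            )
        )
    return GroundTruth(config=config, molecules=molecules)


# ---------------------------------------------------------------------------
# trace rendering


def _ideal_channels(m: MoleculeGroundTruth, config: SimulationConfig):
    """Noiseless donor/acceptor series before leakage, per the E model.

    Pre-acceptor-bleach: donor = I·(1−E), acceptor = γ·I·E (γ as acceptor
    gain); between bleaches: donor = I, acceptor = 0; after donor bleach
    both zero.
    """
    n = config.n_frames
    frames = np.arange(n)
    e = m.true_e[:n]
    donor = np.where(frames < m.acceptor_bleach_frame, config.total_intensity * (1.0 - e),
                     config.total_intensity)
    donor = np.where(frames >= m.donor_bleach_frame, 0.0, donor)
    acceptor = np.where(
        frames < m.acceptor_bleach_frame,
        m.gamma_true * config.total_intensity * e,
        0.0,
    )
    acceptor = np.where(frames >= m.donor_bleach_frame, 0.0, acceptor)
    return donor, acceptor


def _apply_noise(donor, acceptor, config: SimulationConfig, rng):
    """Leakage → background → Poisson → Gaussian, mirroring the signal chain."""
    if config.excitation_noise_sd > 0:
        # common-mode excitation fluctuation hits both dyes identically
        xi = 1.0 + rng.normal(0.0, config.excitation_noise_sd, len(donor))
        donor = donor * xi
        acceptor = acceptor * xi
    acceptor = acceptor + config.leakage * donor
    if config.poisson_noise:
        donor = rng.poisson(np.clip(donor, 0, None)).astype(float)
        acceptor = rng.poisson(np.clip(acceptor, 0, None)).astype(float)
    if config.read_noise_sd > 0:
        donor = donor + rng.normal(0, config.read_noise_sd, len(donor))
        acceptor = acceptor + rng.normal(0, config.read_noise_sd, len(acceptor))
    return donor, acceptor


def render_trace_set(truth: GroundTruth, config: SimulationConfig | None = None):
    """Render per-molecule donor/acceptor traces from ground truth.

    Returns a list of :class:`~stimfret.traces.MoleculeTrace` (raw; leakage
    applied, no background — movie rendering owns background structure).
    """
    config = config or truth.config
    out = []
    for m in truth:
        rng = np.random.default_rng((config.seed, 1, m.molecule_id))
        donor, acceptor = _render_molecule(m, config, rng)
        out.append(
            MoleculeTrace(
                molecule_id=m.molecule_id,
                donor=donor,
                acceptor=acceptor,
                frame_interval=config.frame_interval,
            )
        )
    return out


def _render_molecule(m: MoleculeGroundTruth, config: SimulationConfig, rng):
    if m.defect == "multi_step_bleach":
        donor, acceptor = _ideal_channels(m, config)
        f_a = min(m.acceptor_bleach_frame, config.n_frames)
        f_mid = max(1, f_a - max(15, f_a // 3))
        frames = np.arange(config.n_frames)
        # a second, directly excited acceptor of equal brightness adds a
        # constant component that bleaches earlier with no donor response
        pre = m.true_e[: max(f_a, 1)]
        extra = m.gamma_true * config.total_intensity * float(np.mean(pre))
        acceptor = acceptor + np.where(frames < f_mid, extra, 0.0)
    elif m.defect == "donor_first":
        n = config.n_frames
        frames = np.arange(n)
        f_d = min(m.donor_bleach_frame, n - 20)
        f_a = m.acceptor_bleach_frame
        e = m.true_e[:n]
        donor = np.where(frames < f_d, config.total_intensity * (1.0 - e), 0.0)
        level = m.gamma_true * config.total_intensity * float(np.mean(e[:max(f_d, 1)]))
        acceptor = np.where(frames < f_d, m.gamma_true * config.total_intensity * e, level)
        acceptor = np.where(frames >= f_a, 0.0, acceptor)
    elif m.defect == "uncorrelated":
        # a static molecule whose channels fluctuate independently (e.g. a
        # dye pair too far apart for FRET, the acceptor directly excited):
        # both sit at constant levels, the acceptor with extra white
        # fluctuations, so no anticorrelation links the channels
        n = config.n_frames
        frames = np.arange(n)
        pre = m.true_e[: min(max(m.acceptor_bleach_frame, 1), n)]
        e_mean = float(np.mean(pre))
        donor = np.where(frames < m.acceptor_bleach_frame,
                         config.total_intensity * (1.0 - e_mean), config.total_intensity)
        donor = np.where(frames >= m.donor_bleach_frame, 0.0, donor)
        level = m.gamma_true * config.total_intensity * e_mean
        acceptor = np.where(frames < m.acceptor_bleach_frame, level, 0.0)
        acceptor = np.where(frames >= m.donor_bleach_frame, 0.0, acceptor)
        wiggle = rng.normal(0.0, 0.12 * level, n)
        acceptor = acceptor + np.where(frames < m.acceptor_bleach_frame, wiggle, 0.0)
    else:  # clean and aggregate (γ out of range) share the rendering model
        donor, acceptor = _ideal_channels(m, config)
    return _apply_noise(donor, acceptor, config, rng)


# ---------------------------------------------------------------------------
# planted defects


def plant_defects(truth: GroundTruth, fractions: dict, seed: int = 0) -> GroundTruth:
    """Relabel a seeded subset of molecules with requested defect classes.

    ``fractions`` maps defect labels (all but ``clean``) to fractions of the
    molecule set; counts are ``round(fraction · n)`` under a seeded shuffle,
    so they are deterministic.  Molecules whose bleach cascade would fall
    outside the recording window are planted last (a planted defect should
    actually be observable).  Aggregates get γ_true resampled outside the
    acceptance window.  Re-render traces after planting.
    """
    bad = set(fractions) - set(DEFECT_LABELS[1:])
    if bad:
        raise ValueError(f"unknown defect labels: {sorted(bad)}")
    if sum(fractions.values()) > 1.0 + 1e-9:
        raise ValueError("defect fractions must not sum above 1")
    rng = np.random.default_rng(seed)
    n = len(truth)
    margin = 30
    eligible = np.array(
        [m.acceptor_bleach_frame < truth.config.n_frames - margin for m in truth.molecules]
    )
    order = rng.permutation(n)
    order = np.concatenate([order[eligible[order]], order[~eligible[order]]])
    pos = 0
    for label in DEFECT_LABELS[1:]:
        frac = fractions.get(label, 0.0)
        count = int(round(frac * n))
        for idx in order[pos : pos + count]:
            m = truth.molecules[idx]
            m.defect = label
            if label == "aggregate":
                m.gamma_true = float(rng.choice([0.35, 3.2]))
            elif label == "donor_first":
                # swap the bleach order in the ground truth itself
                f_d = m.acceptor_bleach_frame
                gap = max(10, m.donor_bleach_frame - m.acceptor_bleach_frame)
                m.donor_bleach_frame = f_d
                m.acceptor_bleach_frame = f_d + gap
        pos += count
    return truth


# ---------------------------------------------------------------------------
# movie rendering


@dataclass
class MovieConfig:
    """Geometry of the synthetic two-channel side-by-side movie."""

    height: int = 64
    width: int = 128  # two side-by-side 64-px halves
    psf_sigma: float = 1.2  # pixels
    margin: float = 6.0
    # affine misalignment donor→acceptor half, applied to spot coordinates
    misalignment_matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    misalignment_offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    n_beads: int = 12
    bead_intensity: float = 5000.0
    min_separation: float = 6.0

    @property
    def half_width(self) -> int:
        return self.width // 2


def _paint_spot(image, x, y, amplitude, sigma):
    """Add a 2D Gaussian of total ``amplitude`` at (x, y); truncated at 5σ."""
    r = int(np.ceil(5 * sigma))
    h, w = image.shape
    x0, y0 = int(round(x)), int(round(y))
    ys = np.arange(max(0, y0 - r), min(h, y0 + r + 1))
    xs = np.arange(max(0, x0 - r), min(w, x0 + r + 1))
    if len(ys) == 0 or len(xs) == 0:
        return
    gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
    gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
    kernel = np.outer(gy, gx)
    total = kernel.sum()
    if total > 0:  # normalize within the truncation window: exact conservation
        image[np.ix_(ys, xs)] += amplitude * kernel / total


def assign_positions(truth: GroundTruth, movie: MovieConfig, seed: int | None = None):
    """Place molecules in the donor half and map them through the misalignment."""
    rng = np.random.default_rng(truth.config.seed if seed is None else seed)
    half = movie.half_width
    placed: list[np.ndarray] = []
    for m in truth:
        for _ in range(1000):
            x = rng.uniform(movie.margin, half - movie.margin)
            y = rng.uniform(movie.margin, movie.height - movie.margin)
            p = np.array([x, y])
            if all(np.linalg.norm(p - q) >= movie.min_separation for q in placed):
                break
        else:
            m.overlapping = True
        placed.append(p)
        m.donor_pos = (float(x), float(y))
        acc = movie.misalignment_matrix @ p + movie.misalignment_offset
        m.acceptor_pos = (float(acc[0]), float(acc[1]))
    return truth


def render_movie(truth: GroundTruth, traces, movie: MovieConfig = MovieConfig()):
    """Render the two-channel movie stack and a registration bead pair.

    Each molecule is painted as a Gaussian PSF carrying its per-frame trace
    value: donor in the left half at ``donor_pos``, acceptor in the right
    half at the misaligned ``acceptor_pos``.  Background level plus a linear
    x-gradient is added to every frame.  Returns ``(movie_stack,
    (bead_donor, bead_acceptor))`` as float arrays; write with ``tifffile``.
    """
    cfg = truth.config
    n = cfg.n_frames
    stack = np.zeros((n, movie.height, movie.width), dtype=float)
    xs = np.arange(movie.width)
    background = cfg.background_level + cfg.background_gradient * xs
    stack += background[None, None, :]
    trace_map = {t.molecule_id: t for t in traces}
    for m in truth:
        t = trace_map[m.molecule_id]
        dx, dy = m.donor_pos
        ax, ay = m.acceptor_pos
        for f in range(n):
            if t.donor[f] != 0:
                _paint_spot(stack[f], dx, dy, t.donor[f], movie.psf_sigma)
            if t.acceptor[f] != 0:
                _paint_spot(
                    stack[f], movie.half_width + ax, ay, t.acceptor[f], movie.psf_sigma
                )

    rng = np.random.default_rng((cfg.seed, 99))
    bead_donor = np.zeros((movie.height, movie.half_width), dtype=float)
    bead_acceptor = np.zeros_like(bead_donor)
    for _ in range(movie.n_beads):
        x = rng.uniform(movie.margin, movie.half_width - movie.margin)
        y = rng.uniform(movie.margin, movie.height - movie.margin)
        _paint_spot(bead_donor, x, y, movie.bead_intensity, movie.psf_sigma)
        acc = movie.misalignment_matrix @ np.array([x, y]) + movie.misalignment_offset
        _paint_spot(bead_acceptor, acc[0], acc[1], movie.bead_intensity, movie.psf_sigma)
    return stack, (bead_donor, bead_acceptor)


# ---------------------------------------------------------------------------
# synthetic structures


def _helix_ca(n_res: int, origin, axis, phase: float = 0.0,
              radius: float = 0.23, rise: float = 0.15, twist_deg: float = 100.0):
    """Cα positions of an ideal α-helix along ``axis`` (nm)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    i = np.arange(n_res)
    ang = phase + np.deg2rad(twist_deg) * i
    return (
        np.asarray(origin, float)
        + np.outer(i * rise, axis)
        + radius * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))
    )


def make_synthetic_cad() -> AtomicModel:
    """Synthetic stand-in for the CAD crystal-structure dimer.

    A parallel V-shaped two-chain model, residues 344–443 per chain: the CC2
    helix (345–391) rises from the dimer base, an apex loop (392–407) turns
    over, and the CC3 helix (408–436) folds back alongside CC2; short
    terminal segments complete the range.  Chain B is the exact two-fold
    rotation of chain A about the z axis.  Cα-only, ideal helix geometry —
    a synthetic construction, not an experimental structure.
    """
    coords = {}
    # CC2 rises along +z; CC3 folds back antiparallel at ~0.95 nm axis
    # separation (typical coiled-coil packing distance)
    cc2_axis = np.array([0.0, 0.0, 1.0])
    cc2 = _helix_ca(391 - 345 + 1, origin=(0.55, 0.25, 0.0), axis=cc2_axis)
    for r, p in zip(range(345, 392), cc2):
        coords[r] = p
    # N-terminal residue 344 extends the CC2 direction downward
    coords[344] = cc2[0] - np.array([0.0, 0.0, 0.38])
    cc3_top = np.array([1.50, 0.25, 6.2])
    cc3 = _helix_ca(436 - 408 + 1, origin=cc3_top, axis=(0.0, 0.0, -1.0))
    # apex loop 392..407: a hairpin rising above both helices, resampled to
    # equal spacing so the loop neither crumples nor self-intersects
    start, end = cc2[-1], cc3[0]
    apex_z = max(start[2], end[2]) + 2.3
    waypoints = np.array(
        [start, [start[0], start[1], apex_z], [end[0], end[1], apex_z], end]
    )
    seg = np.diff(waypoints, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    s_cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    targets = np.linspace(0.0, s_cum[-1], 18)[1:-1]  # 16 interior residues
    for r, s in zip(range(392, 408), targets):
        k = int(np.searchsorted(s_cum[1:], s, side="right"))
        frac = (s - s_cum[k]) / seg_len[k]
        coords[r] = waypoints[k] + frac * seg[k]
    for r, p in zip(range(408, 437), cc3):
        coords[r] = p
    # C-terminal tail 437..443 continues the CC3 direction
    for k, r in enumerate(range(437, 444), start=1):
        coords[r] = cc3[-1] + 0.38 * k * np.array([0.0, 0.0, -1.0])

    res = np.array(sorted(coords), dtype=int)
    ca = np.array([coords[r] for r in res])
    rot = np.diag([-1.0, -1.0, 1.0])  # C2 about z
    cb = ca @ rot.T
    n = len(res)
    return AtomicModel(
        element=np.full(2 * n, "C", dtype="U4"),
        atom_name=np.full(2 * n, "CA", dtype="U6"),
        res_id=np.concatenate([res, res]),
        chain_id=np.array(["A"] * n + ["B"] * n, dtype="U4"),
        coord=np.vstack([ca, cb]),
    )


def synthetic_cad_transform() -> SymmetryTransform:
    """The exact A→B transform of :func:`make_synthetic_cad`."""
    return SymmetryTransform(rotation=np.diag([-1.0, -1.0, 1.0]), translation=np.zeros(3))


# ---------------------------------------------------------------------------
# planted CC1 chains


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _arc_directions(delta: np.ndarray, k: int, spacing: float,
                    plane_normal) -> list[np.ndarray]:
    """k unit directions of equal turn whose scaled sum equals ``delta``.

    The directions fan symmetrically in the plane containing ``delta`` and
    perpendicular ``w = normal × delta``, rotating by a constant angle per
    step — a circular-arc walk that lands exactly on the target.
    """
    delta = np.asarray(delta, float)
    length = np.linalg.norm(delta) / spacing
    if length > k + 1e-9:
        raise ValueError("target out of reach for the given step count")
    u = _unit(delta)
    w = np.cross(np.asarray(plane_normal, float), u)
    if np.linalg.norm(w) < 1e-9:
        raise ValueError("plane normal parallel to the target direction")
    w = _unit(w)

    def chord(theta):
        if theta < 1e-9:
            return float(k)
        return np.sin(k * theta / 2) / np.sin(theta / 2)

    lo_t, hi_t = 1e-9, np.pi / 1.001
    # chord() decreases from k toward its first zero; bisect on the branch
    hi_t = min(hi_t, 2 * np.pi / k * 0.999)
    for _ in range(200):
        mid = 0.5 * (lo_t + hi_t)
        if chord(mid) > length:
            lo_t = mid
        else:
            hi_t = mid
    theta = 0.5 * (lo_t + hi_t)
    phi0 = -(k - 1) * theta / 2
    return [np.cos(phi0 + i * theta) * u + np.sin(phi0 + i * theta) * w
            for i in range(k)]


def make_planted_chain(cad: AtomicModel | None = None,
                       transform: SymmetryTransform | None = None) -> NodeChain:
    """Deterministic planted CC1 chain in a stacked configuration.

    Grown from residue 344 (anchored at the CAD N-terminus) down to 233 with
    exact spacings (0.38 nm linker steps, straight helices at 0.15 nm per
    residue, boundary steps at linker spacing).  CC1α3 descends below the
    CAD base, CC1α2 rises back antiparallel alongside the partner subunit's
    CC1α3´ (the stacked class), and CC1α1 continues upward along the lower
    part of the partner CC3´ (the domain-swapped clamp contact).  Subunit B
    is the exact dimer transform of subunit A.  Synthetic ground truth for
    forward-simulating constraint tables.
    """
    if cad is None:
        cad = make_synthetic_cad()
        transform = synthetic_cad_transform()
    if transform is None:
        raise ValueError("transform required when a CAD model is supplied")

    nodes = {CC1_START: cad.ca_coord(CC1_START, "A")}
    pos = nodes[CC1_START]

    def place_arc(res_hi, res_lo, target, normal):
        nonlocal pos
        k = res_hi - res_lo + 1
        for r, d in zip(range(res_hi, res_lo - 1, -1),
                        _arc_directions(target - pos, k, LINKER_SPACING, normal)):
            pos = pos + LINKER_SPACING * d
            nodes[r] = pos

    def place_helix(res_hi, res_lo, direction):
        nonlocal pos
        d = _unit(direction)
        pos = pos + LINKER_SPACING * d  # boundary step into the helix
        nodes[res_hi] = pos
        for r in range(res_hi - 1, res_lo - 1, -1):
            pos = pos + HELIX_SPACING * d
            nodes[r] = pos

    def place_straight(res_hi, res_lo, direction):
        nonlocal pos
        d = _unit(direction)
        for r in range(res_hi, res_lo - 1, -1):
            pos = pos + LINKER_SPACING * d
            nodes[r] = pos

    # helix anchors and axes (see docstring for the intended packing)
    t337 = np.array([1.00, 1.10, -0.80])
    d_a3 = _unit([-0.12, -0.05, -0.99])  # CC1α3 descends below the CAD base
    t305 = np.array([0.20, -0.35, -4.45])
    d_a2 = _unit([-0.10, -0.10, 0.99])  # CC1α2 rises along the partner CC1α3´
    t271 = np.array([-1.35, -0.95, 0.25])
    d_a1 = _unit([0.00, 0.05, 1.00])  # CC1α1 rises along the partner CC3´

    place_arc(343, 338, t337 - LINKER_SPACING * d_a3, normal=(0, 0, 1))
    place_helix(337, 310, d_a3)
    place_arc(309, 306, t305 - LINKER_SPACING * d_a2, normal=(0, 0, -1))
    place_helix(305, 275, d_a2)
    place_arc(274, 272, t271 - LINKER_SPACING * d_a1, normal=(0, -1, 0))
    place_helix(271, 246, d_a1)
    place_straight(245, 233, (-0.55, -0.75, 0.35))

    residues = np.arange(CC1_START, CC1_END - 1, -1)
    coords_a = np.array([nodes[int(r)] for r in residues])
    coords_b = transform.apply(coords_a)
    return NodeChain(residues=residues, coords_a=coords_a, coords_b=coords_b,
                     transform=transform, kind="planted")


# ---------------------------------------------------------------------------
# forward-simulated constraint tables


def default_site_pairs():
    """Synthetic 36-pair site layout for constraint forward simulation.

    Inter-subunit CC1:CC1´ pairs spanning the three helices and linkers plus
    CC1:CAD pairs onto labeled CAD sites — the same classes and roughly the
    same coverage a full measurement campaign provides, but a synthetic
    layout, not the published one.
    """
    cc1_cc1 = [236, 239, 242, 249, 258, 265, 271, 274, 285, 294, 300, 305,
               312, 321, 330, 337, 341]
    cad_sites = [363, 378, 389, 400, 417, 431]
    cc1_cad = [
        (242, 431), (249, 417), (258, 417), (265, 431), (271, 417),
        (274, 431), (285, 363), (294, 378), (300, 389), (305, 400),
        (312, 363), (321, 378), (330, 389), (337, 363), (239, 431),
        (236, 417), (341, 400), (294, 363), (321, 389),
    ]
    pairs = [((r, "A"), (r, "B"), "cc1_cc1") for r in cc1_cc1]
    pairs += [((r, "A"), (s, "B"), "cc1_cad") for r, s in cc1_cad]
    assert len(pairs) == 36
    return pairs, cad_sites


def make_planted_constraints(
    chain: PlantedChain,
    cad: AtomicModel,
    site_pairs=None,
    forster: ForsterConfig = ForsterConfig(),
    jitter: float = 0.0,
    seed: int = 0,
) -> list[DistanceConstraint]:
    """Forward-simulate a constraint table from a planted chain.

    For each pair the true model distance is computed (node-to-node for
    CC1:CC1´, node-to-effective-center for CC1:CAD — effective centers must
    already be attached to ``cad``), converted to a peak efficiency through
    the inverse Förster relation, and optionally jittered by ±``jitter`` in
    E (uniform).  Efficiencies are clipped into (0.02, 0.98) as measured
    peaks would be.
    """
    if site_pairs is None:
        site_pairs, _ = default_site_pairs()
    rng = np.random.default_rng(seed)
    out = []
    for site_a, site_b, pair_class in site_pairs:
        ra, sa = site_a
        if not CC1_END <= ra <= CC1_START:
            raise ValueError(f"CC1 site {ra} outside residue range {CC1_END}-{CC1_START}")
        pa = chain.node(ra, sa)
        if pair_class == "cc1_cc1":
            pb = chain.node(site_b[0], site_b[1])
        else:
            pb = cad.site_coord(site_b[0], site_b[1])
        d = float(np.linalg.norm(pa - pb))
        e = distance_to_fret(d, forster)
        if jitter > 0:
            e = e + rng.uniform(-jitter, jitter)
        e = float(np.clip(e, 0.02, 0.98))
        out.append(
            DistanceConstraint(site_a=site_a, site_b=site_b, pair_class=pair_class,
                               e_peak=e)
        )
    return out
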