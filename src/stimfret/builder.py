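"""Constraint-satisfaction chain growth of CC1 around the CAD dimer.

CC1 chains are grown node by node from residue 344 (anchored at the CAD
N-terminus) down to residue 233.  Linker nodes step 0.38 nm in a random
direction that may not turn the chain by more than 90° per step; helical
segments are placed as single rigid straight runs at 0.15 nm per residue.
After every placement the mirrored partner node is generated through the
dimer's two-fold transform, and both are tested against (a) steric
exclusion — no node center within 0.25 nm of any CAD atom or previously
placed node (chain-adjacent neighbors exempt) — and (b) every smFRET
distance constraint whose two sites are now both placed.  Failed
placements are resampled up to a trial budget, then the builder backtracks
one placement unit.  Constraints that persistently block solutions get
their upper bound relaxed in 1 nm increments; an ensemble of independent
solutions is collected with the relaxed constraint set frozen, averaged,
and classified into stacked versus wedged CC1α2/α3 topologies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from stimfret.chain import (
    CC1_END,
    CC1_HELIX_RANGES,
    CC1_START,
    HELIX_SPACING,
    LINKER_SPACING,
    NodeChain,
)
from stimfret.structure import AtomicModel, SymmetryTransform

__all__ = [
    "BuilderConfig",
    "BuildFailure",
    "SolutionEnsemble",
    "build_chain_solution",
    "relax_and_build",
    "ensemble_build",
    "average_model",
    "classify_topology",
]


@dataclass
class BuilderConfig:
    """Growth parameters for the CC1 chain builder."""

    linker_spacing: float = LINKER_SPACING
    helix_spacing: float = HELIX_SPACING
    exclusion_radius: float = 0.25  # nm
    min_bend_angle: float = 90.0  # degrees; chain may not turn by more
    helix_ranges: dict = field(default_factory=lambda: dict(CC1_HELIX_RANGES))
    start_residue: int = CC1_START
    end_residue: int = CC1_END
    n_solutions: int = 50
    relaxation_increment: float = 1.0  # nm
    max_node_trials: int = 150
    max_backtracks: int = 250
    max_relaxation_rounds: int = 40
    attempts_per_relaxation: int = 3
    direction_set: np.ndarray | None = None  # restrict directions (lattice tests)
    stacked_angle_deg: float = 135.0
    stacked_dist_nm: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.linker_spacing <= 0 or self.helix_spacing <= 0:
            raise ValueError("spacings must be positive")
        if self.start_residue <= self.end_residue:
            raise ValueError("growth runs from high to low residue numbers")
        for name, (lo, hi) in self.helix_ranges.items():
            if not self.end_residue <= lo <= hi <= self.start_residue:
                raise ValueError(f"helix {name} outside the chain range")
        if self.direction_set is not None:
            d = np.asarray(self.direction_set, dtype=float)
            self.direction_set = d / np.linalg.norm(d, axis=1, keepdims=True)

    @property
    def max_turn_cos(self) -> float:
        # the bend angle at a junction must stay >= min_bend_angle, i.e. the
        # chain direction may turn by at most 180 - min_bend_angle
        return float(np.cos(np.deg2rad(180.0 - self.min_bend_angle)))


@dataclass
class BuildFailure:
    """Structured report of an unsuccessful build attempt."""

    deepest_residue: int  # lowest residue number reached before giving up
    backtracks: int
    trials: int
    rejection_counts: dict  # constraint label → rejected placements


@dataclass
class SolutionEnsemble:
    solutions: list  # accepted NodeChains
    labels: list  # stacked | wedged per solution
    constraints: list  # final (possibly relaxed) constraint set
    seeds: list
    trials: int
    backtracks: int
    failures: int

    @property
    def stacked_fraction(self) -> float:
        if not self.labels:
            return float("nan")
        return sum(1 for l in self.labels if l == "stacked") / len(self.labels)


# ---------------------------------------------------------------------------
# growth plan


def _config_spacing(config: BuilderConfig, res_a: int, res_b: int) -> float:
    """Step spacing between adjacent residues under this config's helices."""
    for lo, hi in config.helix_ranges.values():
        if lo <= res_a <= hi and lo <= res_b <= hi:
            return config.helix_spacing
    return config.linker_spacing


def _placement_units(config: BuilderConfig):
    """Sequence of placement units: single linker residues or whole helices.

    Growth is descending, so a helix is entered at its high-residue end.
    """
    units = []
    r = config.start_residue - 1
    by_high = {hi: (name, lo, hi) for name, (lo, hi) in config.helix_ranges.items()}
    while r >= config.end_residue:
        if r in by_high:
            name, lo, hi = by_high[r]
            units.append(("helix", name, list(range(hi, lo - 1, -1))))
            r = lo - 1
        else:
            units.append(("linker", None, [r]))
            r -= 1
    return units


def _is_cc1_residue(res: int) -> bool:
    return CC1_END <= res <= CC1_START


def _index_constraints(constraints):
    """constraint trigger residue → constraints becoming checkable there."""
    by_res: dict[int, list] = {}
    for c in constraints:
        cc1_res = [r for r in (c.site_a[0], c.site_b[0]) if _is_cc1_residue(r)]
        if not cc1_res:  # structure-side constraint; not checked during growth
            continue
        if c.pair_class == "cc1_cad":
            trigger = c.site_a[0] if _is_cc1_residue(c.site_a[0]) else c.site_b[0]
        else:
            trigger = min(cc1_res)
        by_res.setdefault(trigger, []).append(c)
    return by_res


def _batch_directions(rng, prev_dir, config: BuilderConfig, k: int):
    """Up to ``k`` candidate unit directions respecting the bend rule."""
    if config.direction_set is not None:
        dirs = config.direction_set
        if prev_dir is not None:
            dirs = dirs[dirs @ prev_dir >= config.max_turn_cos - 1e-12]
        if len(dirs) == 0:
            return np.empty((0, 3))
        return dirs[rng.integers(len(dirs), size=k)]
    v = rng.normal(size=(2 * k, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if prev_dir is not None:
        v = v[v @ prev_dir >= config.max_turn_cos - 1e-12]
    return v[:k]


def build_chain_solution(
    cad: AtomicModel,
    constraints,
    config: BuilderConfig,
    transform: SymmetryTransform,
    seed: int | None = None,
):
    """Grow one symmetric CC1 chain pair; returns NodeChain or BuildFailure.

    Constraints must already carry bounds (``constraint_bounds``); CAD-side
    sites of cc1_cad constraints need effective centers on ``cad``.
    Candidate directions for each placement unit are evaluated as one
    vectorized batch; the first acceptable candidate (in sample order) is
    kept, so the algorithm is equivalent to sequential rejection sampling.
    """
    for c in constraints:
        if c.lb is None or c.ub is None:
            raise ValueError(f"constraint {c.label} lacks bounds")
        if c.pair_class == "cc1_cad":
            cad_site = c.site_b if _is_cc1_residue(c.site_a[0]) else c.site_a
            if (cad_site[0], cad_site[1]) not in cad.effective_centers:
                raise ValueError(
                    f"no effective dye center for CAD site {cad_site}; run "
                    "attach_effective_centers first"
                )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    radius = config.exclusion_radius
    rot_t = transform.rotation.T
    trans = transform.translation

    cad_mask = cad.res_id != config.start_residue
    cad_tree = cKDTree(cad.coord[cad_mask]) if np.any(cad_mask) else None
    constraints_by_res = _index_constraints(constraints)
    units = _placement_units(config)

    anchor = cad.ca_coord(config.start_residue, "A")
    # placed nodes in placement order; index 0 is the anchor
    placed_res: list[int] = [config.start_residue]
    placed_xyz: list[np.ndarray] = [anchor]
    nodes: dict[int, np.ndarray] = {config.start_residue: anchor}
    placed_units: list[dict] = []
    rejections: dict[str, int] = {}

    def site_point(res, sub):
        if _is_cc1_residue(res) and res in nodes:
            p = nodes[res]
            return p if sub == "A" else p @ rot_t + trans
        return cad.site_coord(res, sub)

    def active_constraints(residues):
        """Constraints fully determined once ``residues`` are placed."""
        placed_after = set(nodes) | set(residues)
        out = []
        for res in residues:
            for c in constraints_by_res.get(res, ()):
                needed = [r for r in (c.site_a[0], c.site_b[0]) if _is_cc1_residue(r)]
                if all(r in placed_after for r in needed):
                    out.append(c)
        return out

    def constraint_mask(cand, residues, active, base):
        """(K,) bool: candidates satisfying every active constraint.

        ``cand`` is (K, m, 3) with columns matching ``residues``; rejections
        are attributed per constraint among sterically valid candidates.
        """
        k_ = cand.shape[0]
        ok = base.copy()
        col = {r: j for j, r in enumerate(residues)}

        def pts(site):
            r, sub = site
            if r in col:
                p = cand[:, col[r], :]
                return p if sub == "A" else p @ rot_t + trans
            return np.broadcast_to(site_point(r, sub), (k_, 3))

        for c in active:
            d = np.linalg.norm(pts(c.site_a) - pts(c.site_b), axis=1)
            good = (d >= c.lb - 1e-12) & (d <= c.ub + 1e-12)
            n_bad = int(np.count_nonzero(ok & ~good))
            if n_bad:
                rejections[c.label] = rejections.get(c.label, 0) + n_bad
            ok &= good
        return ok

    i = 0
    backtracks = 0
    trials = 0
    deepest = config.start_residue
    fail_streak: dict[int, int] = {}
    while i < len(units):
        kind, name, residues = units[i]
        prev_res = residues[0] + 1
        prev_pos = nodes[prev_res]
        prev_dir = placed_units[i - 1]["out_dir"] if i > 0 else None
        dirs = _batch_directions(rng, prev_dir, config, config.max_node_trials)
        trials += len(dirs)
        success = False
        if len(dirs):
            # candidate node coordinates: (K, m, 3)
            steps = np.empty(len(residues))
            steps[0] = _config_spacing(config, prev_res, residues[0])
            steps[1:] = config.helix_spacing
            cum = np.cumsum(steps)
            cand = prev_pos[None, None, :] + dirs[:, None, :] * cum[None, :, None]
            k_, m_ = cand.shape[:2]
            flat = cand.reshape(-1, 3)
            flat_b = flat @ rot_t + trans
            ok = np.ones(k_ * m_, dtype=bool)
            if cad_tree is not None:
                ok &= cad_tree.query(flat)[0] >= radius
                ok[ok] &= cad_tree.query(flat_b[ok])[0] >= radius
            # own mirror
            ok &= np.linalg.norm(flat - flat_b, axis=1) >= radius
            pa = np.asarray(placed_xyz)
            pb = pa @ rot_t + trans
            da = np.linalg.norm(flat[:, None, :] - pa[None, :, :], axis=2)
            db = np.linalg.norm(flat[:, None, :] - pb[None, :, :], axis=2)
            # same-chain adjacency exemption: only the first candidate node
            # is adjacent to the previously placed node
            adj = np.zeros((k_ * m_, len(placed_res)), dtype=bool)
            prev_idx = placed_res.index(prev_res)
            adj[0 :: m_, prev_idx] = True
            ok &= np.all((da >= radius) | adj, axis=1)
            ok &= np.all(db >= radius, axis=1)
            ok_units = ok.reshape(k_, m_).all(axis=1)
            if np.any(ok_units):
                active = active_constraints(residues)
                if active:
                    ok_units = constraint_mask(cand, residues, active, ok_units)
            winners = np.flatnonzero(ok_units)
            if len(winners):
                k_idx = int(winners[0])
                for j, r in enumerate(residues):
                    p = cand[k_idx, j]
                    nodes[r] = p
                    placed_res.append(r)
                    placed_xyz.append(p)
                placed_units.append({"residues": residues, "out_dir": dirs[k_idx]})
                deepest = min(deepest, residues[-1])
                success = True
        if success:
            fail_streak[i] = 0
            i += 1
            continue
        backtracks += 1
        if backtracks > config.max_backtracks or i == 0:
            return BuildFailure(
                deepest_residue=deepest, backtracks=backtracks, trials=trials,
                rejection_counts=dict(rejections),
            )
        # escalate: a unit that keeps failing needs earlier decisions undone,
        # not just its immediate predecessor resampled
        fail_streak[i] = fail_streak.get(i, 0) + 1
        depth = min(1 + fail_streak[i] // 8, i)
        for _ in range(depth):
            last = placed_units.pop()
            for r in last["residues"]:
                nodes.pop(r, None)
                placed_res.pop()
                placed_xyz.pop()
            i -= 1

    residues = np.arange(config.start_residue, config.end_residue - 1, -1)
    coords_a = np.array([nodes[int(r)] for r in residues])
    coords_b = transform.apply(coords_a)
    return NodeChain(
        residues=residues, coords_a=coords_a, coords_b=coords_b,
        transform=transform, kind="solution",
        meta={"seed": int(seed if seed is not None else config.seed),
              "trials": trials, "backtracks": backtracks},
    )


# ---------------------------------------------------------------------------
# relaxation loop


def relax_and_build(cad, constraints, config: BuilderConfig, transform):
    """Relax persistently blocking constraints until a solution exists.

    Repeated build attempts; after each round of failures the constraint
    implicated most often in placement rejections (ties: the one triggered
    deepest in the growth) has its upper bound increased by 1 nm.  Returns
    ``(constraints', first_solution)``.
    """
    constraints = [replace(c) for c in constraints]
    rng = np.random.default_rng(config.seed)
    for round_idx in range(config.max_relaxation_rounds + 1):
        rejections: dict[str, int] = {}
        for _ in range(config.attempts_per_relaxation):
            result = build_chain_solution(
                cad, constraints, config, transform, seed=int(rng.integers(2**31))
            )
            if isinstance(result, NodeChain):
                return constraints, result
            for k, v in result.rejection_counts.items():
                rejections[k] = rejections.get(k, 0) + v
        if round_idx == config.max_relaxation_rounds:
            break
        if not rejections:
            # no constraint implicated: steric dead end; retry fresh seeds
            continue
        triggers = _index_constraints(constraints)
        depth = {}
        for res, cs in triggers.items():
            for c in cs:
                depth[c.label] = res
        worst = max(
            rejections,
            key=lambda lab: (rejections[lab], -depth.get(lab, CC1_START)),
        )
        for c in constraints:
            if c.label == worst:
                c.ub += config.relaxation_increment
                c.n_relaxations += 1
                break
    raise RuntimeError(
        "no solution within the relaxation budget; rejection statistics: "
        f"{rejections}"
    )


def ensemble_build(cad, constraints, config: BuilderConfig, transform) -> SolutionEnsemble:
    """Collect ``n_solutions`` independent validated solutions.

    Bound relaxation is resolved once (``relax_and_build``), then the
    relaxed constraint set is frozen for the whole ensemble.  Every accepted
    solution is re-validated by the independent checker; a solution budget
    of 20× attempts guards against infinite loops (partial ensembles carry a
    warning).
    """
    from stimfret.validate import validate_solution

    constraints, first = relax_and_build(cad, constraints, config, transform)
    solutions = [first]
    rng = np.random.default_rng((config.seed, 7))
    trials = first.meta["trials"]
    backtracks = first.meta["backtracks"]
    failures = 0
    seeds = [first.meta["seed"]]
    max_attempts = 20 * config.n_solutions
    attempts = 0
    while len(solutions) < config.n_solutions and attempts < max_attempts:
        attempts += 1
        seed = int(rng.integers(2**31))
        result = build_chain_solution(cad, constraints, config, transform, seed=seed)
        if isinstance(result, BuildFailure):
            failures += 1
            backtracks += result.backtracks
            trials += result.trials
            continue
        report = validate_solution(result, cad, constraints, config)
        if not report.ok:
            raise AssertionError(f"builder produced an invalid solution: {report.problems}")
        solutions.append(result)
        seeds.append(seed)
        trials += result.meta["trials"]
        backtracks += result.meta["backtracks"]
    if len(solutions) < config.n_solutions:
        warnings.warn(
            f"partial ensemble: {len(solutions)}/{config.n_solutions} solutions"
        )
    labels = [classify_topology(s, config)[0] for s in solutions]
    return SolutionEnsemble(
        solutions=solutions, labels=labels, constraints=constraints,
        seeds=seeds, trials=trials, backtracks=backtracks, failures=failures,
    )


# ---------------------------------------------------------------------------
# averaging and classification


def average_model(solutions, force: bool = False):
    """Average a topology-consistent set of solutions per residue.

    Returns a NodeChain of kind ``"average"`` with per-residue RMS spread.
    The averaged chain does not satisfy spacing invariants and is marked as
    such.  Mixing stacked and wedged solutions raises unless ``force``.
    """
    if len(solutions) < 2:
        raise ValueError("need at least two solutions to average")
    labels = {classify_topology(s)[0] for s in solutions}
    if len(labels) > 1 and not force:
        raise ValueError(
            f"refusing to average across topology classes {sorted(labels)}; "
            "pass force=True to override"
        )
    residues = solutions[0].residues
    a = np.stack([s.coords_a for s in solutions])
    b = np.stack([s.coords_b for s in solutions])
    mean_a = a.mean(axis=0)
    spread = np.sqrt(np.mean(np.sum((a - mean_a) ** 2, axis=2), axis=0))
    return NodeChain(
        residues=residues, coords_a=mean_a, coords_b=b.mean(axis=0),
        transform=solutions[0].transform, kind="average", spread=spread,
        meta={"n_solutions": len(solutions)},
    )


def _segment_min_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum distance between two node runs (dense-node approximation)."""
    d = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2)
    return float(d.min())


def classify_topology(solution: NodeChain, config: BuilderConfig | None = None):
    """Label a solution stacked or wedged from its CC1α2/α3´ packing.

    Stacked: the CC1α2 helix of one subunit packs antiparallel against the
    partner subunit's CC1α3´ — axis angle above ``stacked_angle_deg`` and
    minimal helix–helix distance below ``stacked_dist_nm``.  Returns
    ``(label, diagnostics)``.
    """
    config = config or BuilderConfig()
    try:
        a2 = solution.helix_axis("CC1a2", "A")
        a3p = solution.helix_axis("CC1a3", "B")
    except KeyError:
        # chains built over custom residue ranges lack the helices the
        # classifier is defined on
        return "unclassified", {}
    cosang = float(np.clip(a2 @ a3p, -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    dist = _segment_min_distance(
        solution.helix_nodes("CC1a2", "A"), solution.helix_nodes("CC1a3", "B")
    )
    stacked = angle > config.stacked_angle_deg and dist < config.stacked_dist_nm
    label = "stacked" if stacked else "wedged"
    return label, {"axis_angle_deg": angle, "min_axis_distance_nm": dist}
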