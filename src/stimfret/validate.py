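"""Independent validation of CC1 chain solutions.

Deliberately shares no geometry code with the builder: every invariant is
re-derived here with direct pairwise computations, so a builder bug cannot
hide behind a shared helper.  Checks, per solution:

* exact node spacings (0.38 nm linker / 0.15 nm within-helix, boundary
  steps at linker spacing), to 1e-9 nm;
* exact collinearity of every helical segment;
* bend angles: the chain never turns by more than 90° (or the configured
  limit) at any junction;
* mirror symmetry: subunit B equals the transformed subunit A to 1e-9 nm;
* steric exclusion against all CAD atoms and all non-adjacent nodes of both
  subunits;
* every distance constraint within its (possibly relaxed) bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stimfret.chain import CC1_END, CC1_START, NodeChain

__all__ = ["ValidationReport", "validate_solution"]

SPACING_TOL = 1e-9
SYMMETRY_TOL = 1e-9
COLLINEARITY_TOL = 1e-6


@dataclass
class ValidationReport:
    ok: bool
    problems: list = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.problems.append(msg)
        self.ok = False


def validate_solution(
    solution: NodeChain,
    cad,
    constraints,
    config,
) -> ValidationReport:
    """Check every structural invariant of one accepted solution.

    ``config`` needs ``exclusion_radius``, ``min_bend_angle``,
    ``start_residue`` and ``end_residue`` attributes.
    """
    helix_ranges = getattr(config, "helix_ranges", {})
    linker_spacing = getattr(config, "linker_spacing", 0.38)
    helix_spacing = getattr(config, "helix_spacing", 0.15)

    def label(residue):
        for name, (lo, hi) in helix_ranges.items():
            if lo <= residue <= hi:
                return name
        return "linker"

    def spacing(res_a, res_b):
        la, lb = label(res_a), label(res_b)
        return helix_spacing if (la == lb and la != "linker") else linker_spacing

    report = ValidationReport(ok=True)
    res = solution.residues
    a = solution.coords_a
    b = solution.coords_b

    # residue coverage, descending
    expected = np.arange(config.start_residue, config.end_residue - 1, -1)
    if not np.array_equal(res, expected):
        report.add("residue coverage differs from the configured range")
        return report

    # spacings
    for i in range(len(res) - 1):
        hi, lo = int(res[i]), int(res[i + 1])
        want = spacing(hi, lo)
        got = np.linalg.norm(a[i + 1] - a[i])
        if abs(got - want) > SPACING_TOL:
            report.add(f"spacing {hi}->{lo}: {got:.12f} != {want}")

    # helix collinearity: all within-helix bond vectors parallel
    i = 0
    while i < len(res) - 1:
        lab = label(int(res[i]))
        if lab != "linker":
            j = i
            while j < len(res) - 1 and label(int(res[j + 1])) == lab:
                j += 1
            vecs = np.diff(a[i : j + 1], axis=0)
            if len(vecs) >= 2:
                v0 = vecs[0] / np.linalg.norm(vecs[0])
                for v in vecs[1:]:
                    if np.linalg.norm(np.cross(v0, v / np.linalg.norm(v))) > COLLINEARITY_TOL:
                        report.add(f"helix {lab} not collinear")
                        break
            i = j + 1
        else:
            i += 1

    # bend angles: direction change per step limited to 180 - min_bend_angle
    max_turn_cos = np.cos(np.deg2rad(180.0 - config.min_bend_angle))
    dirs = np.diff(a, axis=0)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    for i in range(len(dirs) - 1):
        if float(dirs[i] @ dirs[i + 1]) < max_turn_cos - 1e-9:
            report.add(
                f"bend violation after residue {int(res[i + 1])}: "
                f"cos={dirs[i] @ dirs[i + 1]:.4f}"
            )

    # mirror symmetry
    mapped = solution.transform.apply(a)
    worst = float(np.max(np.linalg.norm(mapped - b, axis=1)))
    if worst > SYMMETRY_TOL:
        report.add(f"mirror symmetry broken: max deviation {worst:.3e} nm")

    # sterics: nodes vs CAD atoms (anchor residue exempt on both chains)
    cad_mask = cad.res_id != config.start_residue
    cad_xyz = cad.coord[cad_mask]
    all_nodes = np.vstack([a, b])
    all_res = np.concatenate([res, res])
    chain_tag = np.array([0] * len(res) + [1] * len(res))
    node_is_anchor = all_res == config.start_residue
    if len(cad_xyz):
        d = np.linalg.norm(all_nodes[:, None, :] - cad_xyz[None, :, :], axis=2)
        bad = (d.min(axis=1) < config.exclusion_radius) & ~node_is_anchor
        for k in np.flatnonzero(bad):
            report.add(
                f"node {int(all_res[k])} chain {'AB'[chain_tag[k]]} clashes with CAD"
            )

    # sterics: node-node, exempting same-chain adjacent pairs
    n = len(all_nodes)
    dd = np.linalg.norm(all_nodes[:, None, :] - all_nodes[None, :, :], axis=2)
    same_chain = chain_tag[:, None] == chain_tag[None, :]
    adjacent = same_chain & (np.abs(all_res[:, None] - all_res[None, :]) == 1)
    close = (dd < config.exclusion_radius) & ~np.eye(n, dtype=bool) & ~adjacent
    for k, m in zip(*np.nonzero(np.triu(close))):
        report.add(
            f"nodes {int(all_res[k])}{'AB'[chain_tag[k]]} and "
            f"{int(all_res[m])}{'AB'[chain_tag[m]]} within exclusion radius"
        )

    # constraints
    for c in constraints:
        try:
            pa = _site_point(solution, cad, c.site_a)
            pb = _site_point(solution, cad, c.site_b)
        except KeyError as exc:
            report.add(f"constraint {c.label}: {exc}")
            continue
        dist = float(np.linalg.norm(pa - pb))
        if not (c.lb - 1e-9 <= dist <= c.ub + 1e-9):
            report.add(
                f"constraint {c.label} violated: {dist:.3f} nm outside "
                f"[{c.lb:.3f}, {c.ub:.3f}]"
            )
    return report


def _site_point(solution: NodeChain, cad, site):
    res, sub = site
    if CC1_END <= res <= CC1_START and res in set(solution.residues.tolist()):
        return solution.node(res, sub)
    return cad.site_coord(res, sub)
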