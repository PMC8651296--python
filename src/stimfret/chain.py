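"""Coarse-grained CC1 node chains: one dimensionless node per residue.

CC1 (residues 233–344) is modeled as a chain of nodes, each the center of
one residue.  Three segments are α-helical and rigid-straight (CC1α1
246–271, CC1α2 275–305, CC1α3 310–337, at 0.15 nm per residue along the
helix axis); everything else is unstructured linker at 0.38 nm per step.
A boundary step between a linker node and a helix terminus uses the linker
spacing.  Chains come in symmetric pairs: subunit B is subunit A mapped
through the dimer's rigid two-fold transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stimfret.structure import SymmetryTransform

__all__ = [
    "CC1_HELIX_RANGES",
    "CC1_START",
    "CC1_END",
    "LINKER_SPACING",
    "HELIX_SPACING",
    "segment_label",
    "step_spacing",
    "NodeChain",
]

CC1_HELIX_RANGES = {"CC1a1": (246, 271), "CC1a2": (275, 305), "CC1a3": (310, 337)}
CC1_START, CC1_END = 344, 233
LINKER_SPACING, HELIX_SPACING = 0.38, 0.15


def segment_label(residue: int) -> str:
    for name, (lo, hi) in CC1_HELIX_RANGES.items():
        if lo <= residue <= hi:
            return name
    return "linker"


def step_spacing(res_a: int, res_b: int) -> float:
    """Node spacing (nm) for the step between two adjacent residues.

    Helical only when both residues lie in the same helix; every boundary
    or linker step is 0.38 nm.
    """
    la, lb = segment_label(res_a), segment_label(res_b)
    if la == lb and la != "linker":
        return HELIX_SPACING
    return LINKER_SPACING


@dataclass
class NodeChain:
    """A symmetric pair of CC1 node chains (residues descending 344→233)."""

    residues: np.ndarray
    coords_a: np.ndarray  # (n, 3) nm
    coords_b: np.ndarray
    transform: SymmetryTransform
    kind: str = "solution"  # solution | planted | average
    spread: np.ndarray | None = None  # per-residue RMS spread (average kind)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.coords_a = np.asarray(self.coords_a, dtype=float)
        self.coords_b = np.asarray(self.coords_b, dtype=float)
        if not (len(self.residues) == len(self.coords_a) == len(self.coords_b)):
            raise ValueError("residues and coordinates must align")

    def index(self, residue: int) -> int:
        idx = np.flatnonzero(self.residues == residue)
        if len(idx) == 0:
            raise KeyError(f"residue {residue} not in chain")
        return int(idx[0])

    def node(self, residue: int, subunit: str = "A") -> np.ndarray:
        c = self.coords_a if subunit == "A" else self.coords_b
        return c[self.index(residue)]

    def segment_labels(self) -> list:
        return [segment_label(int(r)) for r in self.residues]

    def helix_nodes(self, name: str, subunit: str = "A") -> np.ndarray:
        lo, hi = CC1_HELIX_RANGES[name]
        mask = (self.residues >= lo) & (self.residues <= hi)
        c = self.coords_a if subunit == "A" else self.coords_b
        return c[mask]

    def helix_axis(self, name: str, subunit: str = "A") -> np.ndarray:
        """Unit axis of a helix, oriented from low to high residue number."""
        lo, hi = CC1_HELIX_RANGES[name]
        v = self.node(hi, subunit) - self.node(lo, subunit)
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise ValueError(f"degenerate axis for helix {name}")
        return v / n

    def to_pdb(self, path) -> None:
        """Write the node pair as a pseudo-atom PDB (one CA per residue)."""
        from stimfret.structure import AtomicModel

        n = len(self.residues)
        model = AtomicModel(
            element=np.full(2 * n, "C", dtype="U4"),
            atom_name=np.full(2 * n, "CA", dtype="U6"),
            res_id=np.concatenate([self.residues, self.residues]),
            chain_id=np.array(["A"] * n + ["B"] * n, dtype="U4"),
            coord=np.vstack([self.coords_a, self.coords_b]),
        )
        model.to_pdb(path)
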