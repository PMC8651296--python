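"""Atomic models, dye-center simulation and FRET distance constraints.

Coordinates are held in nanometres throughout (PDB Ångström values are
converted on read and write), because every distance in the modeling chain
— Förster radii, constraint bounds, node spacings — is naturally expressed
in nm.

The dye-center simulation is a geometric accessible-volume sampler: dye
centers are drawn uniformly within the tether-length ball around the label
site's Cα and rejected when they clash with protein atoms.  It replaces an
all-atom simulated-annealing treatment of explicit Cy3/Cy5 fluorophore
models; tether lengths are calibrated so that the mean Cα→center protrusion
of an unobstructed site matches the protrusions such simulations report
(~0.99 nm donor-like, ~1.10 nm acceptor-like).  This is the loosest
geometric approximation in the package and is documented as such in the
methods note.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from stimfret.forster import ForsterConfig, fret_to_distance

__all__ = [
    "AtomicModel",
    "DyeParams",
    "DistanceConstraint",
    "sample_dye_centers",
    "effective_center",
    "attach_effective_centers",
    "constraint_bounds",
    "read_constraints",
    "write_constraints",
    "superpose",
    "symmetrize_dimer",
    "optimize_apex",
]

#: residue ranges (inclusive) of the structured CAD elements used for
#: alignment and apex optimization
PROXIMAL_CC2_RANGE = (345, 378)
DISTAL_CC2_RANGE = (379, 391)
APEX_LOOP_RANGE = (392, 407)
CC3_RANGE = (408, 436)
APEX_PIVOT_RESIDUE = 379  # glycine about which the distal CC2 helix rotates


# ---------------------------------------------------------------------------
# atomic model


@dataclass
class AtomicModel:
    """A protein structure as flat per-atom arrays, coordinates in nm.

    ``effective_centers`` maps a labeled site ``(residue, chain_id)`` to the
    coordinate of the pseudo-atom standing in for the dye pair at that site.
    """

    element: np.ndarray  # (n,) str
    atom_name: np.ndarray  # (n,) str
    res_id: np.ndarray  # (n,) int
    chain_id: np.ndarray  # (n,) str
    coord: np.ndarray  # (n, 3) float, nm
    effective_centers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("atomic coordinates must be finite")
        for ch in np.unique(self.chain_id):
            mask = self.chain_id == ch
            names = self.atom_name[mask]
            rid = self.res_id[mask]
            ca = rid[names == "CA"]
            if len(ca) != len(np.unique(ca)):
                raise ValueError(f"duplicate residues in chain {ch}")

    def __len__(self) -> int:
        return len(self.res_id)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for ch in self.chain_id:
            if ch not in seen:
                seen.append(ch)
        return seen

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_id == chain

    def ca_coord(self, residue: int, chain: str) -> np.ndarray:
        mask = (
            (self.chain_id == chain)
            & (self.res_id == residue)
            & (self.atom_name == "CA")
        )
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"no CA atom for residue {residue} chain {chain}")
        return self.coord[idx[0]]

    def residues(self, chain: str) -> np.ndarray:
        mask = (self.chain_id == chain) & (self.atom_name == "CA")
        return np.unique(self.res_id[mask])

    def site_coord(self, residue: int, chain: str) -> np.ndarray:
        """Effective dye center if attached for the site, else the Cα."""
        key = (int(residue), chain)
        if key in self.effective_centers:
            return np.asarray(self.effective_centers[key], float)
        return self.ca_coord(residue, chain)

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            element=self.element.copy(),
            atom_name=self.atom_name.copy(),
            res_id=self.res_id.copy(),
            chain_id=self.chain_id.copy(),
            coord=self.coord.copy(),
            effective_centers={k: np.array(v) for k, v in self.effective_centers.items()},
        )

    # -- PDB round trip (biotite) -------------------------------------------

    @classmethod
    def from_pdb(cls, path) -> "AtomicModel":
        import biotite.structure.io.pdb as pdb

        f = pdb.PDBFile.read(str(path))
        atoms = f.get_structure(model=1)
        return cls(
            element=np.asarray(atoms.element, dtype="U4"),
            atom_name=np.asarray(atoms.atom_name, dtype="U6"),
            res_id=np.asarray(atoms.res_id, dtype=int),
            chain_id=np.asarray(atoms.chain_id, dtype="U4"),
            coord=np.asarray(atoms.coord, dtype=float) / 10.0,  # Å → nm
        )

    def to_pdb(self, path) -> None:
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        n = len(self)
        atoms = struc.AtomArray(n)
        atoms.coord = self.coord * 10.0  # nm → Å
        atoms.chain_id = self.chain_id
        atoms.res_id = self.res_id
        atoms.atom_name = self.atom_name
        atoms.element = self.element
        atoms.res_name = np.full(n, "ALA", dtype="U5")
        atoms.hetero = np.zeros(n, dtype=bool)
        f = pdb.PDBFile()
        f.set_structure(atoms)
        f.write(str(path))


# ---------------------------------------------------------------------------
# accessible-volume dye sampling


@dataclass(frozen=True)
class DyeParams:
    """Geometric parameters of one tethered-dye accessible-volume model.

    ``tether_length`` is the radius (nm) of the ball around the attachment
    Cα reachable by the dye center; ``clash_radius`` the minimum distance to
    any protein atom; 100 samples per site mirrors the repeat count used for
    explicit-dye simulated annealing.
    """

    dye_id: str = "Cy3-like"
    tether_length: float = 1.35
    clash_radius: float = 0.3
    min_ca_distance: float = 0.2
    n_samples: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tether_length > 0:
            raise ValueError("tether length must be positive")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")


CY3_LIKE = DyeParams(dye_id="Cy3-like", tether_length=1.35)
CY5_LIKE = DyeParams(dye_id="Cy5-like", tether_length=1.50)


@dataclass(frozen=True)
class DyeCloud:
    """Accessible-volume sample cloud for one labeled site."""

    site: tuple  # (residue, chain)
    samples: np.ndarray  # (n, 3) nm
    mean_center: np.ndarray  # (3,) nm — average dye-center location
    mean_protrusion: float  # nm — mean Cα→sample distance over the cloud


def sample_dye_centers(
    model: AtomicModel,
    residue: int,
    chain: str,
    params: DyeParams = CY3_LIKE,
    rng: np.random.Generator | None = None,
) -> DyeCloud:
    """Sample accessible dye-center positions around a site's Cα.

    Positions are drawn uniformly in the ball of radius ``tether_length``
    about the Cα and rejected if they fall within ``clash_radius`` of any
    protein atom or within ``min_ca_distance`` of the attachment Cα itself.
    Raises ``RuntimeError`` if the site is so buried that fewer than 1% of
    proposals are accepted.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ca = model.ca_coord(residue, chain)
    # the attachment Cα itself is exempt from the generic clash test
    own = (
        (model.res_id == residue)
        & (model.chain_id == chain)
        & (model.atom_name == "CA")
    )
    tree = cKDTree(model.coord[~own]) if np.any(~own) else None

    accepted: list[np.ndarray] = []
    n_proposed = 0
    max_proposals = max(10000, 200 * params.n_samples)
    while len(accepted) < params.n_samples:
        batch = 4 * params.n_samples
        u = rng.normal(size=(batch, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = params.tether_length * rng.random(batch) ** (1.0 / 3.0)
        pts = ca + u * radii[:, None]
        ok = radii >= params.min_ca_distance
        if tree is not None:
            d, _ = tree.query(pts)
            ok &= d >= params.clash_radius
        accepted.extend(pts[ok])
        n_proposed += batch
        if n_proposed >= max_proposals and len(accepted) < 0.01 * n_proposed:
            raise RuntimeError(
                f"site {residue}:{chain} appears buried: accessible-volume "
                f"acceptance below 1% ({len(accepted)}/{n_proposed})"
            )
    samples = np.array(accepted[: params.n_samples])
    protrusion = float(np.mean(np.linalg.norm(samples - ca, axis=1)))
    return DyeCloud(
        site=(int(residue), chain),
        samples=samples,
        mean_center=samples.mean(axis=0),
        mean_protrusion=protrusion,
    )


def effective_center(donor_mean: np.ndarray, acceptor_mean: np.ndarray) -> np.ndarray:
    """Midpoint of the donor-like and acceptor-like mean dye centers.

    Labeling is stochastic, so either dye may occupy either site; averaging
    the two mean centers yields a single pseudo-atom per site, and model
    distances are measured midpoint-to-midpoint.
    """
    return 0.5 * (np.asarray(donor_mean, float) + np.asarray(acceptor_mean, float))


def attach_effective_centers(
    model: AtomicModel,
    sites,
    donor_params: DyeParams = CY3_LIKE,
    acceptor_params: DyeParams = CY5_LIKE,
    seed: int = 0,
) -> AtomicModel:
    """Compute and store effective dye centers for ``sites`` on the model.

    ``sites`` is an iterable of ``(residue, chain)`` pairs.  Returns a copy
    of the model with ``effective_centers`` populated.
    """
    out = model.copy()
    rng = np.random.default_rng(seed)
    for residue, chain in sites:
        c3 = sample_dye_centers(out, residue, chain, donor_params, rng)
        c5 = sample_dye_centers(out, residue, chain, acceptor_params, rng)
        out.effective_centers[(int(residue), chain)] = effective_center(
            c3.mean_center, c5.mean_center
        )
    return out


# ---------------------------------------------------------------------------
# distance constraints

PAIR_CLASSES = ("cc1_cad", "cc1_cc1", "cad_cad_inter", "intra_subunit")

#: lower-bound offsets (nm) absorbing the ~1 nm dye linker when one or both
#: sites are bare CC1 nodes without an explicit dye model
_LB_OFFSET = {"cc1_cad": 1.0, "cc1_cc1": 2.0, "cad_cad_inter": 0.0, "intra_subunit": 0.0}


@dataclass
class DistanceConstraint:
    """One smFRET measurement converted to a model distance restraint."""

    site_a: tuple  # (residue, subunit)
    site_b: tuple
    pair_class: str
    e_peak: float
    e_uncertainty: float = 0.05
    d_fret: float | None = None  # nm
    lb: float | None = None
    ub: float | None = None
    n_relaxations: int = 0

    def __post_init__(self) -> None:
        if self.pair_class not in PAIR_CLASSES:
            raise ValueError(
                f"unknown pair class {self.pair_class!r}; expected one of {PAIR_CLASSES}"
            )
        self.site_a = (int(self.site_a[0]), str(self.site_a[1]))
        self.site_b = (int(self.site_b[0]), str(self.site_b[1]))

    @property
    def label(self) -> str:
        (ra, sa), (rb, sb) = self.site_a, self.site_b
        prime = "'" if sa != sb else ""
        return f"{ra}:{rb}{prime}"


def constraint_bounds(
    constraint: DistanceConstraint,
    forster: ForsterConfig = ForsterConfig(),
    eps: float = 1e-6,
) -> DistanceConstraint:
    """Set D_FRET and the [lb, ub] distance window for one constraint.

    The peak efficiency is uncertain by ± one histogram bin width (0.05), so
    the window spans the distances corresponding to ``E ± 0.05``; for pairs
    where one (CC1:CAD) or both (CC1:CC1´) dyes are not explicitly modeled,
    the lower bound is additionally lowered by 1 or 2 nm respectively to
    allow the dye(s) to point away from the partner site.  The lower bound
    is floored at zero.
    """
    if not 0.0 < constraint.e_peak < 1.0:
        raise ValueError(f"E_peak must lie in (0, 1), got {constraint.e_peak}")
    du = constraint.e_uncertainty
    d_fret = fret_to_distance(constraint.e_peak, forster)
    e_hi = min(constraint.e_peak + du, 1.0 - eps)
    e_lo = max(constraint.e_peak - du, eps)
    lb = fret_to_distance(e_hi, forster) - _LB_OFFSET[constraint.pair_class]
    ub = fret_to_distance(e_lo, forster)
    return replace(
        constraint,
        d_fret=float(d_fret),
        lb=float(max(lb, 0.0)),
        ub=float(ub),
        n_relaxations=0,
    )


_CONSTRAINT_COLUMNS = [
    "site_a_res",
    "site_a_sub",
    "site_b_res",
    "site_b_sub",
    "pair_class",
    "E_peak",
]


def write_constraints(constraints, path) -> None:
    """Write the shared constraint-table TSV dialect."""
    rows = [
        {
            "site_a_res": c.site_a[0],
            "site_a_sub": c.site_a[1],
            "site_b_res": c.site_b[0],
            "site_b_sub": c.site_b[1],
            "pair_class": c.pair_class,
            "E_peak": c.e_peak,
        }
        for c in constraints
    ]
    pd.DataFrame(rows, columns=_CONSTRAINT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_constraints(path) -> list[DistanceConstraint]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_CONSTRAINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"constraint table missing columns: {sorted(missing)}")
    return [
        DistanceConstraint(
            site_a=(int(r.site_a_res), str(r.site_a_sub)),
            site_b=(int(r.site_b_res), str(r.site_b_sub)),
            pair_class=str(r.pair_class),
            e_peak=float(r.E_peak),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# rigid superposition and dimer symmetrization


def superpose(mobile: np.ndarray, fixed: np.ndarray):
    """Least-RMSD rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps ``mobile`` onto ``fixed``.
    """
    mobile = np.asarray(mobile, float)
    fixed = np.asarray(fixed, float)
    if mobile.shape != fixed.shape or mobile.shape[0] < 3:
        raise ValueError("need matching point sets with at least 3 points")
    cm, cf = mobile.mean(axis=0), fixed.mean(axis=0)
    h = (mobile - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    rmsd = float(np.sqrt(np.mean(np.sum((mobile @ rot.T + trans - fixed) ** 2, axis=1))))
    return rot, trans, rmsd


@dataclass(frozen=True)
class SymmetryTransform:
    """Rigid transform mapping subunit-A coordinates onto subunit B."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def symmetrize_dimer(
    model: AtomicModel,
    alignment_ranges=(PROXIMAL_CC2_RANGE, CC3_RANGE),
    chain_a: str = "A",
    chain_b: str = "B",
):
    """Replace chain B with a symmetry-transformed copy of chain A.

    The transform is the least-RMSD superposition of chain A's Cα atoms in
    the alignment ranges (by default the proximal CC2 and CC3 helices) onto
    chain B's, so the result is an exactly two-fold-symmetric dimer whose
    shared fold is chain A's.  Returns ``(model, transform)``.
    """
    res_a = set(model.residues(chain_a))
    res_b = set(model.residues(chain_b))
    wanted = [
        r for lo, hi in alignment_ranges for r in range(lo, hi + 1)
    ]
    missing = [r for r in wanted if r not in res_a or r not in res_b]
    if missing:
        raise ValueError(f"alignment residues missing from dimer: {missing}")
    pa = np.array([model.ca_coord(r, chain_a) for r in wanted])
    pb = np.array([model.ca_coord(r, chain_b) for r in wanted])
    rot, trans, rmsd = superpose(pa, pb)
    transform = SymmetryTransform(rotation=rot, translation=trans)

    a_mask = model.chain_mask(chain_a)
    b_mask = model.chain_mask(chain_b)
    other = ~(a_mask | b_mask)
    new_b_coord = transform.apply(model.coord[a_mask])
    out = AtomicModel(
        element=np.concatenate([model.element[a_mask], model.element[a_mask], model.element[other]]),
        atom_name=np.concatenate([model.atom_name[a_mask], model.atom_name[a_mask], model.atom_name[other]]),
        res_id=np.concatenate([model.res_id[a_mask], model.res_id[a_mask], model.res_id[other]]),
        chain_id=np.concatenate(
            [
                model.chain_id[a_mask],
                np.full(a_mask.sum(), chain_b, dtype=model.chain_id.dtype),
                model.chain_id[other],
            ]
        ),
        coord=np.concatenate([model.coord[a_mask], new_b_coord, model.coord[other]]),
    )
    # mirror any chain-A effective centers onto B
    for (res, ch), xyz in model.effective_centers.items():
        if ch == chain_a:
            out.effective_centers[(res, chain_a)] = np.array(xyz)
            out.effective_centers[(res, chain_b)] = transform.apply(np.asarray(xyz))
    return out, transform


def symmetry_residual(model: AtomicModel, transform: SymmetryTransform,
                      chain_a: str = "A", chain_b: str = "B") -> float:
    """Max |T(A) − B| over atoms (nm); 0 for an exactly symmetric dimer."""
    a = model.coord[model.chain_mask(chain_a)]
    b = model.coord[model.chain_mask(chain_b)]
    if len(a) != len(b):
        return np.inf
    return float(np.max(np.linalg.norm(transform.apply(a) - b, axis=1)))


# ---------------------------------------------------------------------------
# apex optimization


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * angle).as_matrix()


APEX_CONSTRAINT_SITES = (388, 389, 399, 400, 401)
APEX_INTRA_PAIR = (431, 389)


def default_apex_constraints(model: AtomicModel) -> list[DistanceConstraint]:
    """Apex restraints from a model's own geometry (self-consistency helper).

    Inter-subunit pairs at residues 388, 389, 399, 400, 401 plus the
    intra-subunit 431:389 pair on both subunits, with D_FRET set to the
    model's current site distances.
    """
    cons = []
    for r in APEX_CONSTRAINT_SITES:
        d = float(np.linalg.norm(model.site_coord(r, "A") - model.site_coord(r, "B")))
        cons.append(
            DistanceConstraint(
                site_a=(r, "A"), site_b=(r, "B"), pair_class="cad_cad_inter",
                e_peak=0.5, d_fret=d, lb=d - 0.3, ub=d + 0.3,
            )
        )
    ra, rb = APEX_INTRA_PAIR
    for ch in ("A", "B"):
        d = float(np.linalg.norm(model.site_coord(ra, ch) - model.site_coord(rb, ch)))
        cons.append(
            DistanceConstraint(
                site_a=(ra, ch), site_b=(rb, ch), pair_class="intra_subunit",
                e_peak=0.5, d_fret=d, lb=d - 0.3, ub=d + 0.3,
            )
        )
    return cons


@dataclass
class ApexResult:
    model: AtomicModel
    tilt_axis_angle: float  # ψ, orientation of the tilt axis (rad)
    tilt_angle: float  # θ, rotation magnitude about that axis (rad)
    objective: float  # Σ (model distance − D_FRET)² at optimum, nm²
    residuals: dict  # constraint label → model distance − D_FRET (nm)
    satisfied: bool  # all constraints within their [lb, ub] windows


def _apex_frame(model: AtomicModel, chain: str = "A"):
    """Pivot and an orthonormal frame ⟂ the distal CC2 helix axis."""
    pivot = model.ca_coord(APEX_PIVOT_RESIDUE, chain)
    lo, hi = DISTAL_CC2_RANGE
    axis = model.ca_coord(hi, chain) - model.ca_coord(lo, chain)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return pivot, e1, e2


def apply_apex_rotation(
    model: AtomicModel,
    transform: SymmetryTransform,
    psi: float,
    theta: float,
    chain_a: str = "A",
    chain_b: str = "B",
) -> AtomicModel:
    """Tilt the distal CC2 helix (379–391) rigidly about the G379 pivot.

    The rotation axis lies in the plane perpendicular to the helix axis at
    orientation ``psi``; ``theta`` is the rotation magnitude.  The apex loop
    (392–407) is re-closed by applying each residue its rigid-body
    displacement scaled linearly to zero at residue 407, and the whole move
    is mirrored onto subunit B through the dimer symmetry transform.
    """
    pivot, e1, e2 = _apex_frame(model, chain_a)
    axis = np.cos(psi) * e1 + np.sin(psi) * e2
    rot = _rotation_about_axis(axis, theta)

    out = model.copy()
    a_mask = out.chain_mask(chain_a)
    coords_a = out.coord[a_mask].copy()
    res_a = out.res_id[a_mask]

    rigid = (res_a >= DISTAL_CC2_RANGE[0]) & (res_a <= DISTAL_CC2_RANGE[1])
    moved = (coords_a[rigid] - pivot) @ rot.T + pivot
    coords_a[rigid] = moved

    lo, hi = APEX_LOOP_RANGE
    for r in range(lo, hi + 1):
        sel = res_a == r
        if not np.any(sel):
            continue
        w = (hi - r) / (hi - (lo - 1))  # 1→0 taper from 391 toward 407
        disp = ((coords_a[sel] - pivot) @ rot.T + pivot) - coords_a[sel]
        coords_a[sel] = coords_a[sel] + w * disp

    out.coord[a_mask] = coords_a
    b_mask = out.chain_mask(chain_b)
    out.coord[b_mask] = transform.apply(coords_a)

    # carry effective centers along with their residues
    for (res, ch), xyz in model.effective_centers.items():
        if ch != chain_a:
            continue
        xyz = np.asarray(xyz, float)
        if DISTAL_CC2_RANGE[0] <= res <= DISTAL_CC2_RANGE[1]:
            new = (xyz - pivot) @ rot.T + pivot
        elif APEX_LOOP_RANGE[0] <= res <= APEX_LOOP_RANGE[1]:
            w = (APEX_LOOP_RANGE[1] - res) / (APEX_LOOP_RANGE[1] - (APEX_LOOP_RANGE[0] - 1))
            new = xyz + w * (((xyz - pivot) @ rot.T + pivot) - xyz)
        else:
            new = xyz
        out.effective_centers[(res, chain_a)] = new
        out.effective_centers[(res, chain_b)] = transform.apply(new)
    return out


def _apex_objective(model: AtomicModel, constraints) -> tuple[float, dict]:
    obj = 0.0
    residuals = {}
    for c in constraints:
        d = float(
            np.linalg.norm(model.site_coord(*c.site_a) - model.site_coord(*c.site_b))
        )
        residuals[c.label + f"@{c.site_a[1]}"] = d - c.d_fret
        obj += (d - c.d_fret) ** 2
    return obj, residuals


def _min_clash_distance(model: AtomicModel, exempt_neighbors: int = 2) -> float:
    """Closest non-bonded approach: same-chain near neighbors are exempt."""
    tree = cKDTree(model.coord)
    best = np.inf
    for i, j in tree.query_pairs(r=0.5):
        if (
            model.chain_id[i] == model.chain_id[j]
            and abs(int(model.res_id[i]) - int(model.res_id[j])) <= exempt_neighbors
        ):
            continue
        best = min(best, float(np.linalg.norm(model.coord[i] - model.coord[j])))
    return best


def optimize_apex(
    model: AtomicModel,
    transform: SymmetryTransform,
    constraints: list[DistanceConstraint],
    clash_distance: float = 0.2,
    coarse_psi_step_deg: float = 20.0,
    coarse_theta_step_deg: float = 5.0,
    max_theta_deg: float = 60.0,
    symmetry_tol: float = 1e-6,
) -> ApexResult:
    """Relax the CAD apex against smFRET distance restraints.

    The distal CC2 helix rotates rigidly about G379 (two angles: tilt-axis
    orientation ψ and tilt magnitude θ); the proximal CC2 and CC3 helices
    stay fixed and the apex loop is re-closed by tapered displacement.  The
    objective is Σ(model distance − D_FRET)² over the restraints; a coarse
    (ψ, θ) grid is followed by Nelder–Mead refinement, and any pose bringing
    two atoms closer than ``clash_distance`` is rejected.

    Requires an exactly symmetric input dimer (run ``symmetrize_dimer``
    first); every constraint must carry ``d_fret`` (see
    ``constraint_bounds``).
    """
    if symmetry_residual(model, transform) > symmetry_tol:
        raise ValueError(
            "input dimer is not symmetric under the supplied transform; "
            "run symmetrize_dimer first"
        )
    for c in constraints:
        if c.d_fret is None:
            raise ValueError(f"constraint {c.label} lacks d_fret; call constraint_bounds")

    def evaluate(params):
        psi, theta = params
        cand = apply_apex_rotation(model, transform, psi, theta)
        if _min_clash_distance(cand) < clash_distance:
            return np.inf, cand, {}
        obj, res = _apex_objective(cand, constraints)
        return obj, cand, res

    best = (np.inf, None, {}, 0.0, 0.0)
    for psi in np.deg2rad(np.arange(0.0, 360.0, coarse_psi_step_deg)):
        for theta in np.deg2rad(np.arange(0.0, max_theta_deg + 1e-9, coarse_theta_step_deg)):
            obj, cand, res = evaluate((psi, theta))
            if obj < best[0]:
                best = (obj, cand, res, psi, theta)

    from scipy.optimize import minimize

    def fun(p):
        return evaluate(p)[0]

    opt = minimize(
        fun, x0=[best[3], best[4]], method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400},
    )
    obj, cand, res = evaluate(opt.x)
    if obj < best[0]:
        best = (obj, cand, res, float(opt.x[0]), float(opt.x[1]))

    obj, cand, res, psi, theta = best
    satisfied = all(
        c.lb is not None
        and c.lb
        <= float(np.linalg.norm(cand.site_coord(*c.site_a) - cand.site_coord(*c.site_b)))
        <= c.ub
        for c in constraints
    )
    if not satisfied:
        warnings.warn("apex optimization left some restraints outside their bounds")
    return ApexResult(
        model=cand, tilt_axis_angle=psi, tilt_angle=theta,
        objective=obj, residuals=res, satisfied=satisfied,
    )
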